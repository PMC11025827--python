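"""Coupled cell–geometry–circulation simulator.

One fixed-step forward-Euler loop advances the eight-component cell state
together with (V_lv, V_a).  Each cardiac cycle restarts the Ca2+ release
pulse; cycles are repeated until the end-diastolic volume settles on a
periodic limit cycle.  All derivatives are evaluated from the same
pre-step values, so the scheme is a clean first-order method; the
reference step is 0.01 ms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from . import _kernel as K
from .params import ModelParams

__all__ = [
    "SimTrace", "CycleEvents", "run_to_limit_cycle", "step",
    "apply_volume_perturbation", "phase_events", "initial_state",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CycleEvents:
    """Per-cycle landmark times (ms since cycle start) and volumes (mL)."""

    t_ej: float | None  # ejection onset (clamp / aortic-valve opening)
    t_es: float | None  # end-systole (aortic valve closure)
    EDV: float
    ESV: float
    ejection_duration: float | None


class SimTrace:
    """Uniformly sampled trajectory of one (or more) cardiac cycles.

    Stores the raw state matrix at full resolution; hydraulic and cellular
    observables are derived lazily from it with the reference formula
    modules, so the stored trace is the single source of truth.
    """

    def __init__(
        self,
        states: np.ndarray,
        dt: float,
        params: ModelParams,
        t_ej_idx: int,
        converged: bool,
        edv_history: np.ndarray,
        n_cycles: int,
    ):
        self.states = states
        self.dt = dt
        self.params = params
        self.t_ej_idx = t_ej_idx
        self.converged = converged
        self.edv_history = edv_history
        self.n_cycles = n_cycles

    # -- raw state columns --------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return np.arange(self.states.shape[0]) * self.dt

    @property
    def t_ej(self) -> float | None:
        return None if self.t_ej_idx < 0 else self.t_ej_idx * self.dt

    @property
    def V_lv(self) -> np.ndarray:
        return self.states[:, K.S_VLV]

    @property
    def V_a(self) -> np.ndarray:
        return self.states[:, K.S_VA]

    @property
    def Ca(self) -> np.ndarray:
        return self.states[:, K.S_CA]

    # -- derived observables ------------------------------------------------
    @cached_property
    def R_lv(self) -> np.ndarray:
        from .lv_geometry import radius_from_volume

        return radius_from_volume(self.V_lv, self.params.geometry)

    @cached_property
    def L(self) -> np.ndarray:
        from .lv_geometry import hsl_from_volume

        return hsl_from_volume(self.V_lv, self.params.geometry)

    @cached_property
    def F_b(self) -> np.ndarray:
        p = self.params.cell
        s = self.states
        h_w = self.L - s[:, K.S_XW]
        h_p = self.L - s[:, K.S_XP]
        return (p.A_w * (s[:, K.S_TSCA3W] + s[:, K.S_TSW]) * h_w
                + p.A_p * (s[:, K.S_TSCA3P] + s[:, K.S_TSP]) * h_p)

    @cached_property
    def F_p(self) -> np.ndarray:
        from .cell_model import passive_force

        return passive_force(self.L, self.params.passive)

    @cached_property
    def F_ext(self) -> np.ndarray:
        from .lv_geometry import wall_tension

        return wall_tension(self.F_b, self.F_p, self.params.geometry)

    @cached_property
    def P_lv(self) -> np.ndarray:
        from .lv_geometry import pressure_from_tension

        return pressure_from_tension(self.F_ext, self.R_lv, self.params.geometry)

    @cached_property
    def P_a(self) -> np.ndarray:
        return self.V_a / self.params.circulation.C_a

    @cached_property
    def flows(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = self.params.circulation
        q_0 = np.maximum((c.P_E1 - self.P_lv) / c.R_pv, 0.0)
        q_in = np.maximum((self.P_lv - self.P_a) / c.R_lo, 0.0)
        q_out = (self.P_a - c.P_E2) / c.R_out
        return q_0, q_in, q_out

    @cached_property
    def phase(self) -> np.ndarray:
        """Phase label per sample: filling where the mitral valve is open,
        ejection where the aortic valve is open, isovolumic otherwise,
        split by which valve was open last."""
        q_0, q_in, _ = self.flows
        n = len(q_0)
        code = np.zeros(n, dtype=np.int8)  # 0 iso, 1 filling, 2 ejection
        code[q_0 > 0] = 1
        code[q_in > 0] = 2
        labels = np.empty(n, dtype=object)
        last = 1  # a cycle starts at end-diastole, after filling
        for i in range(n):
            if code[i] == 1:
                labels[i] = "filling"
                last = 1
            elif code[i] == 2:
                labels[i] = "ejection"
                last = 2
            else:
                labels[i] = ("isovolumic_contraction" if last == 1
                             else "isovolumic_relaxation")
        return labels

    def state_at(self, idx: int) -> np.ndarray:
        return self.states[idx].copy()

    def index_after_ejection(self, t_offset: float) -> int:
        """Grid index of t_ej + t_offset [ms]."""
        if self.t_ej_idx < 0:
            raise ValueError("trace has no ejection onset")
        idx = self.t_ej_idx + round(t_offset / self.dt)
        if not 0 <= idx < self.states.shape[0]:
            raise ValueError(f"t_ej+{t_offset} ms is outside the trace")
        return idx

    def dL_dt_at(self, idx: int) -> float:
        """Centered-difference dL/dt [um/ms] on the full-resolution grid."""
        if not 1 <= idx < self.states.shape[0] - 1:
            raise ValueError("index too close to the trace boundary")
        return (self.L[idx + 1] - self.L[idx - 1]) / (2.0 * self.dt)

    def dataframe(self, decimation: int | None = None) -> pd.DataFrame:
        """Tidy table of the trace; decimation defaults to the config value."""
        d = self.params.sim.store_decimation if decimation is None else decimation
        sl = slice(None, None, d)
        q_0, q_in, q_out = self.flows
        return pd.DataFrame({
            "t": self.t[sl], "V_lv": self.V_lv[sl], "P_lv": self.P_lv[sl],
            "V_a": self.V_a[sl], "P_a": self.P_a[sl], "q0": q_0[sl],
            "qin": q_in[sl], "qout": q_out[sl], "L": self.L[sl],
            "Fb": self.F_b[sl], "Fp": self.F_p[sl], "Fext": self.F_ext[sl],
            "Ca": self.Ca[sl], "phase": self.phase[sl],
        })


def initial_state(params: ModelParams) -> np.ndarray:
    """Relaxed starting state: all troponin free, crossbridge extensions at
    rest for the initial length, [Ca2+] at the pump fixed point, aortic
    volume at the clamp value.  The limit cycle erases this choice."""
    from .cell_model import CellState
    from .lv_geometry import hsl_from_volume

    V0 = params.sim.V_lv_init
    L0 = hsl_from_volume(V0, params.geometry)
    cell = CellState.resting(L0, params.cell, params.ca)
    y = np.empty(10)
    y[:8] = cell.to_array()
    y[K.S_VLV] = V0
    y[K.S_VA] = params.circulation.clamp_Va
    return y


def run_to_limit_cycle(params: ModelParams) -> SimTrace:
    """Integrate repeated cycles until |ΔEDV| between consecutive cycles
    drops below the configured tolerance (or max_cycles is hit, with a
    warning), then record one full cycle at every step and return it."""
    sim = params.sim
    P = K.pack_params(params)
    y = initial_state(params)
    edv, t_ej_cycles, n_run, converged, n_clip, ierr = K.run_cycles(
        y, P, sim.dt, sim.steps_per_cycle, sim.max_cycles, sim.edv_tol
    )
    if ierr == 1:
        raise FloatingPointError(f"non-finite state in cycle {n_run}")
    if ierr == 2:
        raise RuntimeError(f"non-positive volume in cycle {n_run}")
    if n_clip:
        warnings.warn(f"{n_clip} concentration undershoots clipped at zero; "
                      "consider a smaller dt", stacklevel=2)
    if not converged:
        warnings.warn(
            f"limit cycle not reached in {sim.max_cycles} cycles "
            f"(last |dEDV| = {abs(edv[-1] - edv[-2]):.3g} mL)", stacklevel=2)
    for i, e in enumerate(edv):
        log.info("cycle %3d: EDV = %.4f mL", i, e)
    states, t_ej_idx, _ = K.run_trace(y, P, sim.dt, sim.steps_per_cycle, 0.0, False)
    trace = SimTrace(states, sim.dt, params, t_ej_idx, bool(converged),
                     np.asarray(edv), int(n_run))
    if t_ej_idx < 0:
        # no clamp event: ejection onset is the aortic valve opening
        open_idx = np.nonzero(trace.flows[1] > 0.0)[0]
        if open_idx.size:
            trace.t_ej_idx = int(open_idx[0])
    return trace


def step(y: np.ndarray, t_cycle: float, params: ModelParams,
         ej_clamped: bool = False) -> np.ndarray:
    """One forward-Euler step of the coupled state vector (10,)."""
    P = K.pack_params(params)
    states, _, _ = K.run_trace(y.copy(), P, params.sim.dt, 1, t_cycle, ej_clamped)
    out = states[1]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite state after step")
    if out[K.S_VLV] <= 0:
        raise RuntimeError("negative LV volume after step")
    return out


def apply_volume_perturbation(y: np.ndarray, fraction: float) -> np.ndarray:
    """Instantaneously remove ``fraction`` of the LV volume.

    Only V_lv changes: the attachment states X_p, X_w and all
    concentrations cannot jump, so L, h_p, h_w, F_b and P_lv follow the
    new volume through the geometric maps when next evaluated.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    out = y.copy()
    out[K.S_VLV] *= 1.0 - fraction
    return out


def phase_events(trace: SimTrace) -> CycleEvents:
    """Landmarks of one recorded cycle.

    End-systole is the aortic valve closure: the first sample after
    ejection onset where the aortic flow returns to zero.  A missing
    ejection phase (e.g. an extreme afterload never reaching the clamp
    pressure) yields None landmarks.
    """
    _, q_in, _ = trace.flows
    edv = float(trace.V_lv.max())
    esv = float(trace.V_lv.min())
    if trace.t_ej_idx < 0:
        warnings.warn("no ejection onset found in trace", stacklevel=2)
        return CycleEvents(None, None, edv, esv, None)
    after = np.nonzero(q_in[trace.t_ej_idx + 1:] <= 0.0)[0]
    # skip any zero-flow samples in the same instant as the clamp
    start = after[after > 0]
    t_es = None
    if start.size:
        t_es = float((trace.t_ej_idx + 1 + start[0]) * trace.dt)
    return CycleEvents(trace.t_ej, t_es, edv, esv,
                       None if t_es is None else t_es - trace.t_ej)
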