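"""Stand-alone experiments.

* Isovelocity shortening: the cell model alone, [Ca2+] clamped, length
  held then shortened at constant velocity — the protocol that exposes the
  force-velocity transient behind the initial E_load.
* Time-varying elastance model (TVEM): the LV replaced by
  P_lv = E(t)(V_lv - V_0) with a cosine activation waveform, inside the
  same Windkessel circulation and integrator — the structural comparator
  in which instantaneous and load-dependent elastance coincide by
  construction.
"""

from __future__ import annotations

import warnings
from functools import cached_property

import numpy as np
import pandas as pd

from . import _kernel as K
from .params import (CirculationParams, IsovelocityConfig, ModelParams,
                     SimConfig, TVEMParams)

__all__ = [
    "isovelocity_shortening", "tvem_elastance", "tvem_simulate", "TVEMTrace",
    "tvem_measure_E_inst",
]


def isovelocity_shortening(cfg: IsovelocityConfig, params: ModelParams | None = None
                           ) -> pd.DataFrame:
    """Run the cell-only isovelocity protocol for every configured velocity.

    Velocities are given in um/s (converted to um/ms internally).  Returns
    a tidy frame with columns t, v, L, hp, hw, Fb, Fp, hp_ss where hp_ss
    is the analytic steady-state extension for that velocity.
    """
    from .cell_model import CellState, passive_force, steady_state_hp

    params = params or ModelParams()
    P = K.pack_params(params)
    n_steps = round(cfg.total_ms / cfg.dt)
    hold_steps = round(cfg.hold_ms / cfg.dt)
    frames = []
    cell0 = CellState.resting(cfg.L_init, params.cell, params.ca)
    y8 = cell0.to_array()
    for v in cfg.velocities:
        v_ms = v / 1000.0  # um/s -> um/ms
        ys, ls = K.run_cell_clamped(y8.copy(), P, cfg.dt, n_steps, hold_steps,
                                    cfg.Ca, v_ms, cfg.L_init)
        hp = ls - ys[:, K.S_XP]
        hw = ls - ys[:, K.S_XW]
        fb = (params.cell.A_w * (ys[:, K.S_TSCA3W] + ys[:, K.S_TSW]) * hw
              + params.cell.A_p * (ys[:, K.S_TSCA3P] + ys[:, K.S_TSP]) * hp)
        frames.append(pd.DataFrame({
            "t": np.arange(n_steps + 1) * cfg.dt,
            "v": v,
            "L": ls,
            "hp": hp,
            "hw": hw,
            "Fb": fb,
            "Fp": passive_force(ls, params.passive),
            "hp_ss": steady_state_hp(-v_ms, params.cell),
        }))
    return pd.concat(frames, ignore_index=True)


def tvem_elastance(t_cycle, p: TVEMParams):
    """Elastance waveform E(t) [mmHg/mL]: cosine rise over the activation
    time T_s, cosine fall over T_s/2, then the diastolic plateau E_d.
    Continuous at both joins; rejects times outside [0, T_rr]."""
    t = np.asarray(t_cycle, dtype=float)
    if np.any(t < 0) or np.any(t > p.T_rr):
        raise ValueError("t_cycle must lie in [0, T_rr]")
    rise = p.E_d + 0.5 * (p.E_s - p.E_d) * (1.0 - np.cos(np.pi * t / p.T_s))
    fall = p.E_d + 0.5 * (p.E_s - p.E_d) * (1.0 + np.cos(2.0 * np.pi * (t - p.T_s) / p.T_s))
    out = np.where(t <= p.T_s, rise, np.where(t <= 1.5 * p.T_s, fall, p.E_d))
    return out if out.ndim else float(out)


class TVEMTrace:
    """One recorded TVEM cycle, mirroring the SimTrace sampling interface
    (t, V_lv, P_lv, t_ej, index_after_ejection) so the isochronous fits
    run unchanged on it."""

    def __init__(self, states: np.ndarray, dt: float, tvem: TVEMParams,
                 circ: CirculationParams, t_ej_idx: int, converged: bool,
                 edv_history: np.ndarray):
        self.states = states
        self.dt = dt
        self.tvem = tvem
        self.circ = circ
        self.t_ej_idx = t_ej_idx
        self.converged = converged
        self.edv_history = edv_history

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.states.shape[0]) * self.dt

    @property
    def t_ej(self) -> float | None:
        return None if self.t_ej_idx < 0 else self.t_ej_idx * self.dt

    @property
    def V_lv(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def V_a(self) -> np.ndarray:
        return self.states[:, 1]

    @cached_property
    def E(self) -> np.ndarray:
        return tvem_elastance(np.minimum(self.t, self.tvem.T_rr), self.tvem)

    @cached_property
    def P_lv(self) -> np.ndarray:
        return self.E * (self.V_lv - self.tvem.V_0_tvem)

    @cached_property
    def P_a(self) -> np.ndarray:
        return self.V_a / self.circ.C_a

    def index_after_ejection(self, t_offset: float) -> int:
        if self.t_ej_idx < 0:
            raise ValueError("trace has no ejection onset")
        idx = self.t_ej_idx + round(t_offset / self.dt)
        if not 0 <= idx < self.states.shape[0]:
            raise ValueError(f"t_ej+{t_offset} ms is outside the trace")
        return idx


def tvem_simulate(tvem: TVEMParams, circ: CirculationParams | None = None,
                  sim: SimConfig | None = None) -> TVEMTrace:
    """Run the TVEM ventricle inside the Windkessel to its limit cycle and
    record one cycle, with the same ejection-onset clamp protocol."""
    circ = circ or CirculationParams()
    sim = sim or SimConfig()
    Q = K.pack_tvem_params(tvem, circ)
    v = np.array([tvem.V_0_tvem + circ.P_E1 / tvem.E_d, circ.clamp_Va])
    edv, n_run, converged = K.run_tvem_cycles(
        v, Q, sim.dt, sim.steps_per_cycle, sim.max_cycles, sim.edv_tol)
    if not converged:
        warnings.warn(f"TVEM limit cycle not reached in {sim.max_cycles} cycles",
                      stacklevel=2)
    states, t_ej_idx = K.run_tvem_trace(v, Q, sim.dt, sim.steps_per_cycle, 0.0, False)
    return TVEMTrace(states, sim.dt, tvem, circ, t_ej_idx, bool(converged),
                     np.asarray(edv))


def tvem_isochrone(traces: list[TVEMTrace], t_offset: float,
                   t_ref: float | None = None):
    """Isochronous P_lv–V_lv fit for TVEM runs at a common absolute time.

    The TVEM pressure is an explicit function of absolute cycle time,
    P = E(t)(V - V_0), so its isochrone identity (slope = E(t), abscissa
    intercept = V_0) holds for samples taken at one common instant.  The
    reference defaults to the first trace's ejection onset; with the onset
    clamp the crossbridge model's onsets nearly coincide across
    afterloads, so there the distinction is immaterial.
    """
    from .elastance import IsochronousFit, linear_fit

    if t_ref is None:
        if traces[0].t_ej is None:
            raise ValueError("reference trace has no ejection onset")
        t_ref = traces[0].t_ej
    idx = round((t_ref + t_offset) / traces[0].dt)
    xs = np.array([tr.V_lv[idx] for tr in traces])
    ys = np.array([tr.P_lv[idx] for tr in traces])
    slope, intercept, r2 = linear_fit(xs, ys)
    return IsochronousFit(t_offset, xs, ys, slope, intercept, r2)


def tvem_measure_E_inst(trace: TVEMTrace, t_offset: float,
                        fraction: float = 0.0025) -> float:
    """Perturbation elastance on the TVEM, one-step protocol as for the
    cell-based model.  Equals E(t) up to the O(dt) waveform drift because
    the pressure is an explicit function of volume."""
    idx = trace.index_after_ejection(t_offset)
    Q = K.pack_tvem_params(trace.tvem, trace.circ)
    t_cycle = idx * trace.dt
    v_base = trace.states[idx].copy()
    v_pert = v_base.copy()
    v_pert[0] *= 1.0 - fraction
    base, _ = K.run_tvem_trace(v_base, Q, trace.dt, 1, t_cycle, True)
    pert, _ = K.run_tvem_trace(v_pert, Q, trace.dt, 1, t_cycle, True)
    E_next = tvem_elastance(min(t_cycle + trace.dt, trace.tvem.T_rr), trace.tvem)
    P_b = E_next * (base[1, 0] - trace.tvem.V_0_tvem)
    P_p = E_next * (pert[1, 0] - trace.tvem.V_0_tvem)
    return float((P_p - P_b) / (pert[1, 0] - base[1, 0]))
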