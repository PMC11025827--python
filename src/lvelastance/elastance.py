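"""Elastance measurements and derived fits.

Two distinct elastances are measured on the simulated ventricle:

* ``E_inst`` — the physical chamber stiffness dP_lv/dV_lv, measured by an
  instantaneous fractional volume drop and the pressure response one step
  later, within a single run;
* ``E_load`` — the slope of the ordinary-least-squares line through
  isochronous (V_lv, P_lv) points collected across afterload (R_out)
  runs, the quantity the classical end-systolic pressure-volume relation
  generalizes.

The isochronous F_ext–L analogue (slope ``k_a``), a closed-form
approximation of E_inst from the power-state occupancy, the initial
E_load approximation from the force-velocity transient, and the
dF_ext/dt vs dL/dt linearity diagnostic are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel as K
from .params import ModelParams
from .simulator import SimTrace, apply_volume_perturbation, run_to_limit_cycle

__all__ = [
    "IsochronousFit", "ElastanceSeries", "linear_fit", "measure_E_load",
    "measure_ka", "measure_E_inst", "E_inst_approx", "E_inst_approx_series",
    "E_load_init_approx", "rate_linearity_diagnostic", "run_elastance_study",
]


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2).

    R^2 = 1 - SS_res/SS_tot; if SS_tot is zero the fit is declared perfect
    (R^2 = 1) when the residuals are also zero.  All-identical x is
    rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values")
    # centered closed form: well conditioned even for the tightly clustered
    # abscissae of late isochrones
    xc = x - x.mean()
    yc = y - y.mean()
    slope = float(xc @ yc) / float(xc @ xc)
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


@dataclass(frozen=True)
class IsochronousFit:
    """OLS line through one isochrone (one point per afterload run)."""

    t_offset: float  # ms after ejection onset
    x: np.ndarray  # V_lv [mL] or L [um]
    y: np.ndarray  # P_lv [mmHg] or F_ext [mN/mm^2]
    slope: float  # E_load [mmHg/mL] or k_a [mN/mm^2/um]
    intercept: float
    r2: float

    @property
    def V_0(self) -> float:
        """Abscissa intercept -intercept/slope (the V_lv-axis crossing)."""
        return -self.intercept / self.slope


def _isochrone_points(traces: list[SimTrace], t_offset: float, xattr: str, yattr: str):
    xs, ys = [], []
    for tr in traces:
        try:
            idx = tr.index_after_ejection(t_offset)
        except ValueError as err:
            raise ValueError(
                f"t_ej+{t_offset} ms unavailable for R_out="
                f"{tr.params.circulation.R_out}: {err}") from err
        xs.append(getattr(tr, xattr)[idx])
        ys.append(getattr(tr, yattr)[idx])
    return np.array(xs), np.array(ys)


def measure_E_load(traces: list[SimTrace], t_offset: float) -> IsochronousFit:
    """Fit the isochronous P_lv–V_lv line at t_ej + t_offset across runs."""
    x, y = _isochrone_points(traces, t_offset, "V_lv", "P_lv")
    slope, intercept, r2 = linear_fit(x, y)
    return IsochronousFit(t_offset, x, y, slope, intercept, r2)


def measure_ka(traces: list[SimTrace], t_offset: float) -> IsochronousFit:
    """Fit the isochronous F_ext–L line at t_ej + t_offset across runs."""
    x, y = _isochrone_points(traces, t_offset, "L", "F_ext")
    slope, intercept, r2 = linear_fit(x, y)
    return IsochronousFit(t_offset, x, y, slope, intercept, r2)


def _pv_of_state(y: np.ndarray, params: ModelParams) -> tuple[float, float]:
    """(V_lv, P_lv) of a raw coupled state vector."""
    from .cell_model import CellState, active_force, passive_force
    from .lv_geometry import (hsl_from_volume, pressure_from_tension,
                              radius_from_volume, wall_tension)

    V = float(y[K.S_VLV])
    L = hsl_from_volume(V, params.geometry)
    s = CellState.from_array(y[:8])
    F_b = active_force(s, L, params.cell)
    F_p = passive_force(L, params.passive)
    F_ext = wall_tension(F_b, F_p, params.geometry)
    P = pressure_from_tension(F_ext, radius_from_volume(V, params.geometry),
                              params.geometry)
    return V, float(P)


def measure_E_inst(trace: SimTrace, t_offset: float, fraction: float = 0.0025,
                   require_ejection: bool = True) -> float:
    """Instantaneous elastance [mmHg/mL] at t_ej + t_offset.

    The run is branched: V_lv is reduced by ``fraction`` with the
    crossbridge attachment states frozen, both branches advance one dt
    step, and the ratio of the pressure to the volume difference between
    them is returned (positive: both differences are negative).
    """
    idx = trace.index_after_ejection(t_offset)
    if require_ejection and trace.phase[idx] != "ejection":
        raise ValueError(
            f"t_ej+{t_offset} ms is in phase {trace.phase[idx]!r}, not ejection")
    params = trace.params
    P = K.pack_params(params)
    t_cycle = idx * trace.dt
    y_base = trace.state_at(idx)
    y_pert = apply_volume_perturbation(y_base, fraction)
    base, _, _ = K.run_trace(y_base, P, trace.dt, 1, t_cycle, True)
    pert, _, _ = K.run_trace(y_pert, P, trace.dt, 1, t_cycle, True)
    V_b, P_b = _pv_of_state(base[1], params)
    V_p, P_p = _pv_of_state(pert[1], params)
    return (P_p - P_b) / (V_p - V_b)


def E_inst_approx(y: np.ndarray, params: ModelParams) -> float:
    """Closed-form E_inst estimate [mmHg/mL] from the power-state occupancy:
    2*K_u*h_lv*K_L*K_R*K_S*A_p*([TSCa3*]+[TS*]) / R_lv.

    Neglects the passive and weak-state stiffness terms and the radius
    derivative of Laplace's law, which the full decomposition shows are
    two orders of magnitude smaller during ejection.
    """
    g = params.geometry
    pw = y[K.S_TSCA3P] + y[K.S_TSP]
    r_lv = g.K_R * y[K.S_VLV] + g.K_V
    return float(2.0 * g.K_u * g.h_lvED * g.K_L * g.K_R * g.K_S
                 * params.cell.A_p * pw / r_lv)


def E_inst_approx_series(trace: SimTrace) -> np.ndarray:
    """Vectorized :func:`E_inst_approx` over a whole trace."""
    g = trace.params.geometry
    pw = trace.states[:, K.S_TSCA3P] + trace.states[:, K.S_TSP]
    return (2.0 * g.K_u * g.h_lvED * g.K_L * g.K_R * g.K_S
            * trace.params.cell.A_p * pw / trace.R_lv)


def E_load_init_approx(y: np.ndarray, delta_t: float, L_dot: float,
                       params: ModelParams) -> tuple[float, float]:
    """Initial-slope approximation of E_load [mmHg/mL] from the
    force-velocity transient at ejection onset.

    Builds ΔL = L_dot*Δt/2 and ΔF_ext = A_p*([TSCa3*]+[TS*])*L_dot/B and
    assembles ΔP/ΔV = 2*K_u*h_lv*ΔF_ext*K_L*K_R/(R_lv*ΔL).  L_dot cancels
    and the result scales as 1/Δt.  The second return value is the
    collapsed closed form K_L*K_R*K_u*h_lv*A_p*pw/(R_lv*B*Δt), which
    differs from the assembled expression by a constant factor; both are
    reported for comparison.
    """
    if L_dot == 0.0:
        raise ValueError("L_dot must be nonzero")
    if not delta_t > 0:
        raise ValueError("delta_t must be > 0")
    g = params.geometry
    c = params.cell
    pw = y[K.S_TSCA3P] + y[K.S_TSP]
    r_lv = g.K_R * y[K.S_VLV] + g.K_V
    dL = 0.5 * L_dot * delta_t
    dF_ext = c.A_p * pw * L_dot / c.B
    assembled = 2.0 * g.K_u * g.h_lvED * dF_ext * g.K_L * g.K_R / (r_lv * dL)
    collapsed = g.K_L * g.K_R * g.K_u * g.h_lvED * c.A_p * pw / (r_lv * c.B * delta_t)
    return float(assembled), float(collapsed)


def rate_linearity_diagnostic(traces: list[SimTrace], t_offset: float,
                              stencil_ms: float = 1.0) -> tuple[float, float, float]:
    """Fit dF_ext/dt against dL/dt across afterloads at t_ej + t_offset.

    Rates are centered finite differences with a 1 ms stencil, wide enough
    to smooth Euler noise without biasing the slopes.  Returns (slope,
    intercept, R^2); the model predicts near-perfect linearity, which is
    what makes the isochronous P–V relation a line.
    """
    if len(traces) < 3:
        raise ValueError("need at least 3 afterload runs")
    dF, dL = [], []
    for tr in traces:
        idx = tr.index_after_ejection(t_offset)
        h = round(stencil_ms / tr.dt)
        if not h <= idx < tr.states.shape[0] - h:
            raise ValueError("stencil exceeds trace bounds")
        dF.append((tr.F_ext[idx + h] - tr.F_ext[idx - h]) / (2 * stencil_ms))
        dL.append((tr.L[idx + h] - tr.L[idx - h]) / (2 * stencil_ms))
    return linear_fit(dL, dF)


@dataclass
class ElastanceSeries:
    """Elastance table over time offsets, with the runs that produced it."""

    times: tuple[float, ...]
    R_outs: tuple[float, ...]
    fraction: float
    fits: dict[float, IsochronousFit]  # P_lv-V_lv isochrones
    ka_fits: dict[float, IsochronousFit]  # F_ext-L isochrones
    E_inst: pd.DataFrame  # rows: times, columns: R_out
    traces: list[SimTrace] = field(default_factory=list, repr=False)

    def table7(self) -> pd.DataFrame:
        """E_inst (first afterload), E_load, V_0 and R^2 per time offset."""
        ref = self.R_outs[0]
        rows = [{
            "t": t,
            "E_inst": self.E_inst.loc[t, ref],
            "E_load": self.fits[t].slope,
            "V_0": self.fits[t].V_0,
            "R2": self.fits[t].r2,
        } for t in self.times]
        return pd.DataFrame(rows)

    def table8(self) -> pd.DataFrame:
        """Isochronous F_ext–L slope k_a and its R^2 per time offset."""
        rows = [{"t": t, "k_a": self.ka_fits[t].slope, "R2": self.ka_fits[t].r2}
                for t in self.times]
        return pd.DataFrame(rows)


DEFAULT_R_OUTS = (1050.0, 1200.0, 1400.0, 1650.0, 2050.0)
DEFAULT_TIMES = (50.0, 100.0, 150.0, 200.0, 250.0, 280.0)


def run_elastance_study(
    params: ModelParams | None = None,
    R_outs: tuple[float, ...] = DEFAULT_R_OUTS,
    times: tuple[float, ...] = DEFAULT_TIMES,
    fraction: float = 0.0025,
    keep_traces: bool = True,
) -> ElastanceSeries:
    """Run the full afterload experiment and measure both elastances.

    For each R_out the coupled model is run to its limit cycle with the
    ejection-onset clamp; isochronous fits and perturbation elastances are
    then taken at every time offset.
    """
    params = params or ModelParams()
    traces = [run_to_limit_cycle(params.with_R_out(r)) for r in R_outs]
    fits = {t: measure_E_load(traces, t) for t in times}
    ka_fits = {t: measure_ka(traces, t) for t in times}
    einst = pd.DataFrame(index=list(times), columns=list(R_outs), dtype=float)
    for tr, r in zip(traces, R_outs):
        for t in times:
            einst.loc[t, r] = measure_E_inst(tr, t, fraction)
    return ElastanceSeries(tuple(times), tuple(R_outs), fraction, fits, ka_fits,
                           einst, traces if keep_traces else [])
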