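"""NL08 myocyte contraction model: troponin-system kinetics, crossbridge
mechanics, phenomenological Ca2+ handling, and passive elastic force.

Three troponins are treated as one cooperative unit ("troponin system",
TS) that binds three Ca2+ ions at once.  The system cycles through five
tracked states — TSCa3, the crossbridge-forming weak states TSCa3~ / TS~
and power states TSCa3* / TS* — with free TS closed by conservation of the
total concentration ``TS_tot``.  Crossbridges act as springs: force is
stiffness x occupancy x elastic extension (h_w = L - X_w, h_p = L - X_p),
and the inextensible portions X slide toward the resting extensions at
rate ``B``.

All functions are NumPy-vectorized in their first arguments.  The
fixed-step simulation loop uses an equivalent JIT kernel
(:mod:`lvelastance._kernel`); the tests assert both agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import CaParams, CellParams, PassiveParams

__all__ = [
    "CellState",
    "detachment_rates",
    "active_force",
    "passive_force",
    "passive_force_slope",
    "ca_release",
    "ca_pump",
    "cell_derivatives",
    "cell_step",
    "steady_state_hp",
    "force_length_slopes",
]


@dataclass(frozen=True)
class CellState:
    """Instantaneous cell state: five troponin-system pools [uM], the
    inextensible crossbridge portions X_p, X_w [um] and [Ca2+] [uM]."""

    TSCa3: float = 0.0
    TSCa3w: float = 0.0
    TSCa3p: float = 0.0
    TSp: float = 0.0
    TSw: float = 0.0
    X_p: float = 0.0
    X_w: float = 0.0
    Ca: float = 0.1

    _FIELDS = ("TSCa3", "TSCa3w", "TSCa3p", "TSp", "TSw", "X_p", "X_w", "Ca")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS])

    @classmethod
    def from_array(cls, a) -> "CellState":
        return cls(**dict(zip(cls._FIELDS, (float(x) for x in a))))

    def bound_total(self) -> float:
        """Sum of the five tracked troponin-system pools [uM]."""
        return self.TSCa3 + self.TSCa3w + self.TSCa3p + self.TSp + self.TSw

    @classmethod
    def resting(cls, L: float, p: CellParams, cp: CaParams) -> "CellState":
        """Fully relaxed cell at length L: all troponin free, crossbridge
        extensions at their resting values, [Ca2+] at the pump fixed point."""
        return cls(X_p=L - p.h_pr, X_w=L - p.h_wr, Ca=cp.ca_rest)


def _check_finite(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"non-finite input {name!r}")


def detachment_rates(L, h_w, dXw_dt, p: CellParams):
    """Crossbridge detachment rates g, g_d [1/ms] and the active extension
    sensitivity gamma_m [1/um^2].

    Detachment accelerates with the squared deviation of the weak-state
    extension from rest; while the weak crossbridges are lengthening
    (dX_w/dt > 0, the filling phase) the sensitivity is attenuated by
    K_gamma, which is the model's filling-phase modification.
    """
    _check_finite(L=L, h_w=h_w, dXw_dt=dXw_dt)
    if not np.all(np.asarray(L) > 0):
        raise ValueError("L must be > 0")
    gamma_m = np.where(np.asarray(dXw_dt) > 0.0, p.gamma / p.K_gamma, p.gamma)
    ex = np.exp(-gamma_m * (h_w - p.h_wr) ** 2)
    g = p.Z_a + p.Y_v * (1.0 - ex)
    g_d = p.Y_d + p.Y_c * (L - p.L_c) ** 2 + p.Y_vd * (1.0 - ex)
    return g, g_d, gamma_m


def active_force(s: CellState, L, p: CellParams):
    """Active crossbridge force F_b [mN/mm^2] at half-sarcomere length L."""
    h_w = L - s.X_w
    h_p = L - s.X_p
    return p.A_w * (s.TSCa3w + s.TSw) * h_w + p.A_p * (s.TSCa3p + s.TSp) * h_p


def passive_force(L, p: PassiveParams):
    """Passive elastic force F_p [mN/mm^2]: linear compressive branch below
    the slack length L_0, exponential above; continuous and zero at L_0."""
    L = np.asarray(L, dtype=float)
    out = np.where(
        L < p.L_0,
        -p.K_PL * (1.0 - L / p.L_0),
        p.K_PE * (np.exp(p.D * (np.minimum(L / p.L_0, 20.0) - 1.0)) - 1.0),
    )
    return out if out.ndim else float(out)


def passive_force_slope(L, p: PassiveParams):
    """dF_p/dL [mN/mm^2/um], the derivative of each branch."""
    L = np.asarray(L, dtype=float)
    out = np.where(
        L < p.L_0,
        p.K_PL / p.L_0,
        p.K_PE * p.D / p.L_0 * np.exp(p.D * (np.minimum(L / p.L_0, 20.0) - 1.0)),
    )
    return out if out.ndim else float(out)


def ca_release(t_cycle, cp: CaParams):
    """SR Ca2+ release Q_rel [uM/ms]: a pulse peaking at t_1 with amplitude
    Q_m, on top of the constant resting leak Q_pump_rest."""
    x = np.asarray(t_cycle, dtype=float) / cp.t_1
    out = cp.Q_m * x ** 4 * np.exp(4.0 * (1.0 - x)) + cp.Q_pump_rest
    return out if out.ndim else float(out)


def ca_pump(Ca, cp: CaParams):
    """SR Ca2+ uptake Q_pump [uM/ms], a Hill-type function of [Ca2+] with
    half-maximum at K_m; the Ca -> 0 limit is 0."""
    Ca = np.asarray(Ca, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(Ca > 0.0, cp.K_p / (1.0 + (cp.K_m / np.maximum(Ca, 1e-300)) ** 2), 0.0)
    return out if out.ndim else float(out)


def cell_derivatives(
    s: CellState, L: float, dL_dt: float, t_cycle: float, p: CellParams, cp: CaParams
) -> CellState:
    """Time derivatives of all eight cell-state components.

    Free troponin is obtained by conservation, TS = TS_tot - (tracked
    pools), and must be non-negative.  The Ca2+ balance subtracts
    ca_stoich * I_troponin, where I_troponin is the net rate at which
    troponin systems enter the Ca-bound pools and ca_stoich (default 3)
    is the number of ions each cooperative system binds.  Returns a
    CellState whose fields hold d/dt values.
    """
    _check_finite(L=L, dL_dt=dL_dt, t_cycle=t_cycle)
    ts_free = p.TS_tot - s.bound_total()
    if ts_free < -1e-9 * p.TS_tot:
        raise ValueError(f"negative free troponin ({ts_free:.3g} uM): corrupted state")
    h_p = L - s.X_p
    h_w = L - s.X_w
    dXp = p.B * (h_p - p.h_pr)
    dXw = p.B * (h_w - p.h_wr)
    g, g_d, _ = detachment_rates(L, h_w, dXw, p)

    ca3 = s.Ca ** 3
    att = p.f * np.exp(-p.R_gauss * (L - p.L_a) ** 2)
    d_tsca3 = p.Y_b * ts_free * ca3 - p.Z_b * s.TSCa3 + g * s.TSCa3w - att * s.TSCa3
    d_tsca3w = att * s.TSCa3 - g * s.TSCa3w + p.Z_p * s.TSCa3p - p.Y_p * s.TSCa3w
    d_tsca3p = p.Y_p * s.TSCa3w - p.Z_p * s.TSCa3p + p.Z_r * s.TSp * ca3 - p.Y_r * s.TSCa3p
    d_tsp = p.Y_r * s.TSCa3p - p.Z_r * s.TSp * ca3 + p.Z_q * s.TSw - p.Y_q * s.TSp
    d_tsw = p.Y_q * s.TSp - p.Z_q * s.TSw - g_d * s.TSw

    i_troponin = d_tsca3 + d_tsca3w + d_tsca3p
    d_ca = ca_release(t_cycle, cp) - ca_pump(s.Ca, cp) - p.ca_stoich * i_troponin
    return CellState(
        TSCa3=d_tsca3, TSCa3w=d_tsca3w, TSCa3p=d_tsca3p, TSp=d_tsp, TSw=d_tsw,
        X_p=dXp, X_w=dXw, Ca=d_ca,
    )


def cell_step(
    s: CellState, L: float, dL_dt: float, t_cycle: float, dt: float,
    p: CellParams, cp: CaParams,
) -> CellState:
    """One forward-Euler update of the cell state.

    Concentrations that undershoot zero are clipped (with a warning); this
    only happens at step sizes well above the reference 0.01 ms.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    d = cell_derivatives(s, L, dL_dt, t_cycle, p, cp)
    new = s.to_array() + dt * d.to_array()
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("non-finite cell state after Euler step")
    conc = np.array([0, 1, 2, 3, 4, 7])
    if np.any(new[conc] < 0.0):
        warnings.warn("concentration undershoot clipped at zero; reduce dt", stacklevel=2)
        new[conc] = np.maximum(new[conc], 0.0)
    return CellState.from_array(new)


def steady_state_hp(dL_dt, p: CellParams):
    """Steady-state power crossbridge extension under constant-velocity
    shortening: h_p,ss = dL/dt / B + h_pr [um].  h_p relaxes toward this
    value exponentially at rate B, which is the origin of the model's
    force-velocity relation."""
    return np.asarray(dL_dt) / p.B + p.h_pr if np.ndim(dL_dt) else dL_dt / p.B + p.h_pr


def force_length_slopes(s: CellState, L, p: CellParams, pp: PassiveParams):
    """(dF_b/dL, dF_p/dL) at frozen attachment state [mN/mm^2/um]."""
    dFb_dL = p.A_w * (s.TSCa3w + s.TSw) + p.A_p * (s.TSCa3p + s.TSp)
    return dFb_dL, passive_force_slope(L, pp)
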