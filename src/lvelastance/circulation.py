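"""Windkessel circulation: constant pulmonary-venous and peripheral
pressures, three series resistances, one aortic compliance, ideal diode
valves, and the ejection-onset clamping protocol.

The clamp makes every afterload run start ejection from the same
pressure-volume point: at the first upward crossing of ``clamp_P`` during
isovolumic contraction, the aortic volume (hence pressure) is reset once
to (clamp_Va, clamp_P) and everything then evolves freely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .params import CirculationParams

__all__ = ["HemoState", "aortic_pressure", "valve_flows", "hemo_derivatives",
           "ejection_onset_clamp"]

PHASES = ("filling", "isovolumic_contraction", "ejection", "isovolumic_relaxation")


@dataclass(frozen=True)
class HemoState:
    """Circulation state plus derived quantities filled by the simulator."""

    t: float = 0.0  # absolute time [ms]
    t_cycle: float = 0.0  # time since cycle start [ms]
    V_lv: float = 130.0  # [mL]
    V_a: float = 105.0  # [mL]
    P_lv: float = 0.0  # [mmHg]
    P_a: float = 70.0  # [mmHg]
    q_0: float = 0.0  # mitral inflow [mL/ms]
    q_in: float = 0.0  # aortic flow [mL/ms]
    q_out: float = 0.0  # peripheral flow [mL/ms]
    R_lv: float = 0.0  # [cm]
    h_lv: float = 1.35  # [cm]
    L: float = 0.0  # [um]
    F_ext: float = 0.0  # [mN/mm^2]
    F_b: float = 0.0
    F_p: float = 0.0
    phase: str = "filling"
    ej_clamped: bool = False  # clamp already fired this cycle

    @property
    def V_tot(self) -> float:
        return self.V_lv + self.V_a


def aortic_pressure(V_a, c: CirculationParams):
    """P_a [mmHg] of the linear aortic compliance: V_a / C_a."""
    return V_a / c.C_a


def valve_flows(P_lv, P_a, c: CirculationParams):
    """(q_0, q_in, q_out) [mL/ms].

    Mitral and aortic valves are ideal diodes in series with R_pv and R_lo;
    the peripheral branch is a plain resistance, so q_out is positive
    whenever P_a exceeds the venous pressure P_E2.
    """
    q_0 = max((c.P_E1 - P_lv) / c.R_pv, 0.0)
    q_in = max((P_lv - P_a) / c.R_lo, 0.0)
    q_out = (P_a - c.P_E2) / c.R_out
    return q_0, q_in, q_out


def hemo_derivatives(s: HemoState, c: CirculationParams):
    """(dV_lv/dt, dV_a/dt) [mL/ms] from the flows of the current state."""
    q_0, q_in, q_out = valve_flows(s.P_lv, s.P_a, c)
    return q_0 - q_in, q_in - q_out


def ejection_onset_clamp(s: HemoState, c: CirculationParams) -> HemoState:
    """Apply the one-instant ejection-onset reset if it is armed.

    Triggered at the first upward crossing of clamp_P during isovolumic
    contraction: V_a is set to clamp_Va (hence P_a = clamp_P), V_lv is not
    modified, and the state is marked so the clamp cannot refire this
    cycle.  With the clamp disabled or already fired, the state is
    returned unchanged.
    """
    if not c.clamp_enabled or s.ej_clamped or s.P_lv < c.clamp_P:
        return s
    return replace(
        s,
        V_a=c.clamp_Va,
        P_a=aortic_pressure(c.clamp_Va, c),
        ej_clamped=True,
    )
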