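"""Parameter containers for the coupled cell–geometry–circulation model.

Every field carries the units used throughout the package (ms, mL, mmHg,
μm, μM, mN/mm²).  Defaults are the published values of the lumped
circulation model, the linear LV geometry maps and the NL08 myocyte
contraction model; the few constants the source tables do not print
(``TS_tot``, ``C_a``, TVEM elastances) are documented at their field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

__all__ = [
    "CellParams",
    "CaParams",
    "PassiveParams",
    "GeometryParams",
    "CirculationParams",
    "SimConfig",
    "TVEMParams",
    "IsovelocityConfig",
    "ModelParams",
]


def _require_positive(obj: Any, names: tuple[str, ...]) -> None:
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {value!r}")


def _require_finite(obj: Any) -> None:
    import math

    for f in fields(obj):
        value = getattr(obj, f.name)
        if isinstance(value, (int, float)) and not math.isfinite(value):
            raise ValueError(f"{type(obj).__name__}.{f.name} is not finite: {value!r}")


@dataclass(frozen=True)
class CellParams:
    """Rate and stiffness constants of the NL08 contraction model.

    The troponin system treats three troponins as one cooperative unit that
    binds three Ca2+ ions; crossbridges exist in a weak (~) and a power (*)
    state whose elastic extensions h_w, h_p generate force.
    """

    A_p: float = 2700.0  # power-state crossbridge stiffness [mN/mm^2/um/uM]
    A_w: float = 540.0  # weak-state crossbridge stiffness [mN/mm^2/um/uM]
    h_pr: float = 0.006  # resting power-state extension [um]
    h_wr: float = 0.0001  # resting weak-state extension [um]
    B: float = 0.5  # crossbridge sliding rate [1/ms]
    Y_b: float = 0.1816  # Ca binding rate [1/uM^3/ms]
    Y_c: float = 1.0  # length-dependent detachment [1/ms/um^2]
    Y_d: float = 0.0333  # baseline weak-state dissociation [1/ms]
    Y_p: float = 0.1397  # weak->power rate [1/ms]
    Y_q: float = 0.2328  # TS* -> TS~ rate [1/ms]
    Y_r: float = 0.1397  # TSCa3* -> TS* rate [1/ms]
    Y_v: float = 1.5  # extension-dependent detachment amplitude (g) [1/ms]
    Y_vd: float = 1.5  # extension-dependent detachment amplitude (g_d) [1/ms]
    Z_a: float = 0.0023  # baseline crossbridge dissociation [1/ms]
    Z_b: float = 0.1397  # Ca unbinding rate [1/ms]
    Z_p: float = 0.2095  # power->weak rate [1/ms]
    Z_q: float = 0.3724  # TS~ -> TS* rate [1/ms]
    Z_r: float = 7.2626  # TS* + 3Ca -> TSCa3* rate [1/uM^3/ms]
    L_c: float = 1.2  # reference length of the L-dependent detachment [um]
    K_gamma: float = 85.3  # detachment attenuation while lengthening [-]
    gamma: float = 28000.0  # detachment extension sensitivity [1/um^2]
    f: float = 0.0023  # crossbridge attachment rate [1/ms]
    R_gauss: float = 15.0  # width of the attachment-rate Gaussian [1/um^2]
    L_a: float = 1.15  # centre of the attachment-rate Gaussian [um]
    # Total troponin-system concentration.  Not printed in the source tables;
    # one troponin system = three troponins, so the physiological ~70 uM of
    # troponin gives 70/3 = 23.3 uM of systems, which also reproduces the
    # published ejection-onset volume at the limit cycle.
    TS_tot: float = 23.3  # [uM]
    # Ca2+ ions bound per troponin system: the Ca balance subtracts
    # ca_stoich * I_troponin.  The cooperative unit binds three ions.
    ca_stoich: float = 3.0

    def __post_init__(self) -> None:
        _require_finite(self)
        _require_positive(
            self,
            (
                "A_p", "A_w", "h_pr", "h_wr", "B", "Y_b", "Y_c", "Y_d", "Y_p",
                "Y_q", "Y_r", "Y_v", "Y_vd", "Z_a", "Z_b", "Z_p", "Z_q", "Z_r",
                "L_c", "K_gamma", "gamma", "f", "R_gauss", "L_a", "TS_tot",
                "ca_stoich",
            ),
        )


@dataclass(frozen=True)
class CaParams:
    """Phenomenological sarcoplasmic-reticulum Ca2+ release/uptake constants."""

    Q_m: float = 3.2  # peak release rate [uM/ms]
    t_1: float = 8.0  # time to peak release [ms]
    Q_pump_rest: float = 0.03  # uptake at the resting point [uM/ms]
    K_p: float = 0.15  # maximal pump rate [uM/ms]
    K_m: float = 0.2  # [Ca2+] at half-maximal pump rate [uM]

    def __post_init__(self) -> None:
        _require_finite(self)
        _require_positive(self, ("Q_m", "t_1", "Q_pump_rest", "K_p", "K_m"))

    @property
    def ca_rest(self) -> float:
        """Resting [Ca2+] [uM]: the fixed point of pump = Q_pump_rest."""
        return self.K_m / (self.K_p / self.Q_pump_rest - 1.0) ** 0.5


@dataclass(frozen=True)
class PassiveParams:
    """Exponential passive elastic force of the half-sarcomere."""

    K_PE: float = 0.2692  # exponential amplitude [mN/mm^2]
    K_PL: float = 7.561  # compressive slope below slack length [mN/mm^2]
    D: float = 28.08  # exponential steepness [-]
    L_0: float = 1.043  # slack half-sarcomere length [um]

    def __post_init__(self) -> None:
        _require_finite(self)
        _require_positive(self, ("K_PE", "K_PL", "D", "L_0"))


@dataclass(frozen=True)
class GeometryParams:
    """Linear volume→radius→half-sarcomere maps, Laplace and unit constants."""

    K_R: float = 0.012  # dR_lv/dV_lv [cm/mL]
    K_V: float = 1.03  # radius at zero volume [cm]
    K_L: float = 0.163  # dL/dR_lv [um/cm]
    L_b: float = 0.682  # half-sarcomere length intercept [um]
    K_S: float = 7.24  # cellular-force scale factor [-]
    K_u: float = 7.50064  # unit conversion [mmHg/(mN/mm^2)]
    h_lvED: float = 1.35  # constant LV wall thickness [cm]

    def __post_init__(self) -> None:
        _require_finite(self)
        _require_positive(self, ("K_R", "K_L", "K_S", "K_u", "h_lvED"))


@dataclass(frozen=True)
class CirculationParams:
    """Windkessel circulation: constant source/sink pressures, three
    resistances, one aortic compliance, ideal valves, and the
    ejection-onset clamp protocol."""

    P_E1: float = 10.0  # pulmonary venous pressure [mmHg]
    P_E2: float = 15.0  # peripheral (venous) pressure [mmHg]
    R_pv: float = 27.0  # pulmonary venous resistance [mmHg*ms/mL]
    R_lo: float = 2.0  # aortic (valve) resistance [mmHg*ms/mL]
    R_out: float = 1050.0  # peripheral resistance (afterload) [mmHg*ms/mL]
    # C_a is not printed; it is forced to clamp_Va/clamp_P = 105/70 = 1.5 by
    # the aortic pressure-volume relation at the clamp point.
    C_a: float = 1.5  # aortic compliance [mL/mmHg]
    clamp_enabled: bool = True
    clamp_P: float = 70.0  # aortic pressure at ejection onset [mmHg]
    clamp_Va: float = 105.0  # aortic volume at ejection onset [mL]
    clamp_hold: bool = False  # hold P_a fixed for the whole ejection

    def __post_init__(self) -> None:
        _require_finite(self)
        _require_positive(self, ("R_pv", "R_lo", "R_out", "C_a", "clamp_P", "clamp_Va"))


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for the coupled fixed-step Euler loop."""

    dt: float = 0.01  # step [ms]
    T_rr: float = 1000.0  # cycle length [ms]
    max_cycles: int = 100
    edv_tol: float = 1e-4  # limit-cycle tolerance on end-diastolic V_lv [mL]
    V_lv_init: float = 130.0  # initial LV volume guess [mL]
    store_decimation: int = 100  # trace thinning factor (100 -> 1 ms samples)

    def __post_init__(self) -> None:
        _require_finite(self)
        _require_positive(self, ("dt", "T_rr", "edv_tol", "V_lv_init"))
        if self.max_cycles < 1:
            raise ValueError("SimConfig.max_cycles must be >= 1")
        n = self.T_rr / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("SimConfig.T_rr must be an integral number of dt steps")
        if self.store_decimation < 1:
            raise ValueError("SimConfig.store_decimation must be >= 1")

    @property
    def steps_per_cycle(self) -> int:
        return round(self.T_rr / self.dt)


@dataclass(frozen=True)
class TVEMParams:
    """Time-varying elastance model of the LV (Heldt-type cosine waveform).

    E_d, E_s and V_0 are not fixed by the reference tables; defaults follow
    the Heldt lumped circulation literature.
    """

    E_d: float = 0.1  # end-diastolic elastance [mmHg/mL]
    E_s: float = 2.5  # end-systolic elastance [mmHg/mL]
    T_rr: float = 1000.0  # cycle length [ms]
    V_0_tvem: float = 15.0  # zero-pressure volume [mL]

    def __post_init__(self) -> None:
        _require_finite(self)
        _require_positive(self, ("E_d", "E_s", "T_rr"))
        if not self.E_s > self.E_d:
            raise ValueError("TVEMParams requires E_s > E_d")
        if 1.5 * self.T_s > self.T_rr:
            raise ValueError("TVEMParams requires 1.5*T_s <= T_rr")

    @property
    def T_s(self) -> float:
        """Duration of LV activation [ms] (Bazett scaling, 0.3 * T_rr)."""
        return 0.3 * self.T_rr


@dataclass(frozen=True)
class IsovelocityConfig:
    """Isovelocity-shortening cell experiment at clamped [Ca2+]."""

    Ca: float = 0.3  # clamped [Ca2+] [uM]
    velocities: tuple[float, ...] = (0.1, 0.15, 0.20)  # shortening [um/s]
    hold_ms: float = 100.0  # isometric hold before shortening [ms]
    total_ms: float = 400.0
    L_init: float = 1.09717  # ejection-onset half-sarcomere length [um]
    dt: float = 0.01

    def __post_init__(self) -> None:
        _require_finite(self)
        _require_positive(self, ("Ca", "hold_ms", "total_ms", "L_init", "dt"))
        if not all(v > 0 for v in self.velocities):
            raise ValueError("IsovelocityConfig velocities must be > 0")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter bundle for the coupled model."""

    cell: CellParams = field(default_factory=CellParams)
    ca: CaParams = field(default_factory=CaParams)
    passive: PassiveParams = field(default_factory=PassiveParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    circulation: CirculationParams = field(default_factory=CirculationParams)
    sim: SimConfig = field(default_factory=SimConfig)

    _NAMESPACES = ("cell", "ca", "passive", "geometry", "circulation", "sim")

    def with_R_out(self, R_out: float) -> "ModelParams":
        return replace(self, circulation=replace(self.circulation, R_out=R_out))

    def to_dict(self) -> dict[str, dict[str, Any]]:
        out: dict[str, dict[str, Any]] = {}
        for ns in self._NAMESPACES:
            sub = getattr(self, ns)
            out[ns] = {f.name: getattr(sub, f.name) for f in fields(sub)}
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParams":
        """Build a bundle from a (possibly partial) nested mapping.

        Omitted keys fall back to the published defaults; unknown namespaces
        or keys raise, as typo protection.
        """
        types = {
            "cell": CellParams,
            "ca": CaParams,
            "passive": PassiveParams,
            "geometry": GeometryParams,
            "circulation": CirculationParams,
            "sim": SimConfig,
        }
        kwargs: dict[str, Any] = {}
        for ns, sub in (data or {}).items():
            if ns not in types:
                raise KeyError(f"unknown config namespace {ns!r}")
            valid = {f.name for f in fields(types[ns])}
            bad = set(sub) - valid
            if bad:
                raise KeyError(f"unknown key(s) in '{ns}': {sorted(bad)}")
            kwargs[ns] = types[ns](**sub)
        return cls(**kwargs)
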