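"""LV geometry: linear maps between cavity volume, internal radius and
half-sarcomere length, and Laplace's law linking wall tension to pressure.

The ventricle is treated as a thin spherical shell of constant wall
thickness ``h_lvED``; the volume→radius and radius→length maps are linear
fits to measured time courses, so the composite V_lv → L map is linear
with slope K_L*K_R.
"""

from __future__ import annotations

import numpy as np

from .params import GeometryParams

__all__ = [
    "radius_from_volume",
    "volume_from_radius",
    "hsl_from_volume",
    "wall_tension",
    "pressure_from_tension",
    "tension_from_pressure",
]


def radius_from_volume(V_lv, g: GeometryParams):
    """LV internal radius R_lv [cm] from cavity volume [mL]."""
    return g.K_R * np.asarray(V_lv) + g.K_V if np.ndim(V_lv) else g.K_R * V_lv + g.K_V


def volume_from_radius(R_lv, g: GeometryParams):
    """Exact inverse of :func:`radius_from_volume`."""
    return (R_lv - g.K_V) / g.K_R


def hsl_from_volume(V_lv, g: GeometryParams):
    """Half-sarcomere length L [um] from cavity volume [mL]."""
    return g.K_L * radius_from_volume(V_lv, g) + g.L_b


def wall_tension(F_b, F_p, g: GeometryParams):
    """Wall tension F_ext [mN/mm^2] = K_S*F_b + F_p; the scale factor K_S
    absorbs the uncertain effective cross-section of cell preparations and
    multiplies the active force only."""
    return g.K_S * F_b + F_p


def pressure_from_tension(F_ext, R_lv, g: GeometryParams, h_lv: float | None = None):
    """Cavity pressure P_lv [mmHg] by Laplace's law for a thin shell:
    P = 2*K_u*F_ext*h_lv / R_lv."""
    if h_lv is None:
        h_lv = g.h_lvED
    R_lv = np.asarray(R_lv, dtype=float)
    if np.any(R_lv <= 0) or (np.ndim(h_lv) == 0 and h_lv <= 0):
        raise ValueError("R_lv and h_lv must be > 0")
    out = 2.0 * g.K_u * np.asarray(F_ext) * h_lv / R_lv
    return out if out.ndim else float(out)


def tension_from_pressure(P_lv, R_lv, g: GeometryParams, h_lv: float | None = None):
    """Exact inverse of :func:`pressure_from_tension`."""
    if h_lv is None:
        h_lv = g.h_lvED
    R_lv = np.asarray(R_lv, dtype=float)
    if np.any(R_lv <= 0):
        raise ValueError("R_lv must be > 0")
    out = np.asarray(P_lv) * R_lv / (2.0 * g.K_u * h_lv)
    return out if out.ndim else float(out)
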