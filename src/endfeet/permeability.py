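"""Transport coefficients of the endfoot sheath.

The sheath is treated as a thin perforated membrane: all exchange between
the perivascular space and the interstitium passes through the narrow
inter-endfoot gaps (width ``d_g``, tortuous path length ``l_g`` through the
overlapping sheath of thickness ``h_ES``, ``l_g >= h_ES``).

* Diffusion: flux per unit sheath area is ``F_D = C_M * D * dc`` with the
  diffusion membrane coefficient ``C_M = alpha * phi_g / l_g`` (m^-1);
  ``alpha`` in [0, 1] accounts for steric/hydrodynamic hindrance in the gap
  (Renkin-type for larger solutes, 1 for small molecules).
* Fluid: the gap is a parallel-plate channel with transmissibility
  ``t_g = d_g^3 / (12 * mu * l_g)``, giving the filtration coefficient
  ``L_p = phi_g * t_g / d_g = phi_g * d_g^2 / (12 * mu * l_g)``
  (m Pa^-1 s^-1) and flow rate ``Q = S * L_p * dp``.

Geometric inputs are given in the micro-scale units they are measured in
(``d_g`` in nm, ``l_g``/``h_ES`` in µm) and converted to SI exactly once
inside these functions; all outputs are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "GapGeometry",
    "FluidProperties",
    "TransportCoefficients",
    "Fluxes",
    "gap_transmissibility",
    "filtration_coefficient",
    "membrane_diffusion_coefficient",
    "transport_coefficients",
    "transmembrane_fluxes",
    "renkin_hindrance",
    "peclet_number",
    "sheath_geometry_from_lumen",
]

#: Classical slit/pore hindrance polynomial coefficients (centerline
#: approximation): alpha = (1-l)^2 * (1 - 2.104 l + 2.09 l^3 - 0.95 l^5).
RENKIN_COEFFS = (2.104, 2.09, 0.95)

#: Gap path length as a multiple of the sheath thickness (endfoot overlap).
L_G_OVER_H_ES = 1.5


@dataclass(frozen=True)
class GapGeometry:
    """Geometry of the inter-endfoot gap channel.

    d_g_nm : gap width in nm (default 20, electron-microscopy value).
    l_g_um : tortuous gap path length in µm.
    h_ES_um : endfoot sheath thickness in µm (``l_g >= h_ES``).
    alpha : hindrance/obstruction factor in [0, 1].
    """

    d_g_nm: float = 20.0
    l_g_um: float = 1.0
    h_ES_um: float | None = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.d_g_nm <= 0 or self.l_g_um <= 0:
            raise ValueError("d_g and l_g must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.h_ES_um is not None and self.l_g_um < self.h_ES_um - 1e-12:
            raise ValueError("l_g must be >= h_ES")

    @property
    def d_g_m(self) -> float:
        return self.d_g_nm * 1e-9

    @property
    def l_g_m(self) -> float:
        return self.l_g_um * 1e-6


@dataclass(frozen=True)
class FluidProperties:
    """mu: dynamic viscosity (Pa s, water at 37 °C by default);
    D: free binary diffusion coefficient (m²/s, small-molecule scale)."""

    mu: float = 0.7e-3
    D: float = 1.0e-9

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.D <= 0:
            raise ValueError("mu and D must be positive")


class TransportCoefficients(NamedTuple):
    t_g: float    # parallel-plate transmissibility d^3/(12 mu l), m^3/(Pa s) per m
    L_p: float    # filtration coefficient, m Pa^-1 s^-1
    C_M: float    # diffusion membrane coefficient, m^-1


class Fluxes(NamedTuple):
    F_D: float                  # diffusive flux per area, (units of dc)·m/s
    Q: float                    # volumetric flow rate, m^3/s
    diffusion_capacity: float   # S * C_M (normalized by D), m
    filtration_capacity: float  # S * L_p, m^3 Pa^-1 s^-1


def _check_phi(phi_g) -> None:
    phi = np.asarray(phi_g, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("phi_g must lie in [0, 1)")


def gap_transmissibility(gap: GapGeometry, fluid: FluidProperties) -> float:
    """Parallel-plate hydraulic transmissibility ``d_g^3 / (12 mu l_g)``."""
    return gap.d_g_m**3 / (12.0 * fluid.mu * gap.l_g_m)


def filtration_coefficient(phi_g, gap: GapGeometry, fluid: FluidProperties = FluidProperties()):
    """Filtration coefficient ``L_p = phi_g * d_g^2 / (12 mu l_g)`` in
    m Pa^-1 s^-1."""
    _check_phi(phi_g)
    return phi_g * gap.d_g_m**2 / (12.0 * fluid.mu * gap.l_g_m)


def membrane_diffusion_coefficient(phi_g, gap: GapGeometry):
    """Diffusion membrane coefficient ``C_M = alpha * phi_g / l_g`` in m^-1."""
    _check_phi(phi_g)
    return gap.alpha * phi_g / gap.l_g_m


def transport_coefficients(
    phi_g: float, gap: GapGeometry, fluid: FluidProperties = FluidProperties()
) -> TransportCoefficients:
    return TransportCoefficients(
        t_g=gap_transmissibility(gap, fluid),
        L_p=filtration_coefficient(phi_g, gap, fluid),
        C_M=membrane_diffusion_coefficient(phi_g, gap),
    )


def transmembrane_fluxes(
    C_M: float,
    L_p: float,
    S: float,
    D: float,
    delta_c: float = 0.0,
    delta_p: float = 0.0,
) -> Fluxes:
    """Fluxes across a sheath patch of area ``S`` (m², all SI).

    ``F_D = C_M * D * delta_c`` is the diffusive flux per unit area and
    ``Q = S * L_p * delta_p`` the volumetric filtration rate; the capacity
    products ``S*C_M`` (diffusion capacity normalized by D) and ``S*L_p``
    are reported alongside.
    """
    if S < 0:
        raise ValueError("surface area must be non-negative")
    return Fluxes(
        F_D=C_M * D * delta_c,
        Q=S * L_p * delta_p,
        diffusion_capacity=S * C_M,
        filtration_capacity=S * L_p,
    )


def renkin_hindrance(lambda_ratio) -> float:
    """Hindrance factor for a solute of diameter ``lambda_ratio * d_g``.

    ``alpha = (1-l)^2 (1 - 2.104 l + 2.09 l^3 - 0.95 l^5)`` clamped to
    [0, 1]; 1 in the free-diffusion limit, 0 when the solute fills the gap.
    """
    lam = np.asarray(lambda_ratio, dtype=float)
    if np.any(lam < 0) or np.any(lam > 1):
        raise ValueError("lambda_ratio must lie in [0, 1]")
    a, b, c = RENKIN_COEFFS
    val = (1.0 - lam) ** 2 * (1.0 - a * lam + b * lam**3 - c * lam**5)
    val = np.clip(val, 0.0, 1.0)
    return float(val) if np.isscalar(lambda_ratio) else val


def peclet_number(delta_p: float, gap: GapGeometry, fluid: FluidProperties) -> float:
    """Gap Péclet number ``Pe_g = dp * d_g^2 / (12 mu alpha D)``.

    Ratio of advective to diffusive transport through the gap channel for a
    pressure drop ``delta_p`` (Pa) across the sheath.
    """
    if gap.alpha <= 0:
        raise ValueError("alpha must be positive for a Péclet number")
    return delta_p * gap.d_g_m**2 / (12.0 * fluid.mu * gap.alpha * fluid.D)


class SheathGeometry(NamedTuple):
    h_ES_um: float
    l_g_um: float
    r_o_um: float


def sheath_geometry_from_lumen(r_v: float) -> SheathGeometry:
    """Sheath geometry implied by the vessel *lumen* radius ``r_v`` (µm).

    The sheath thickness grows linearly with caliber,
    ``h_ES = 1 + 0.15*(r_v - 3)`` µm, clamped below at 1 µm (the in-vivo
    range is 1-2.5 µm); the gap path length is ``l_g = 1.5*h_ES``.  The
    outer radius adds perivascular layers: for ``r_v >= 3`` µm a smooth
    muscle layer of thickness ~h_ES sits under the sheath, giving
    ``r_o = 2*h_ES + 0.4 + r_v = 1.3*r_v + 1.5``; below 3 µm only the
    sheath and the 0.4 µm endothelium/basement membrane remain,
    ``r_o = 1.15*r_v + 0.95``.  The jump at 3 µm is a feature of the data
    (onset of the smooth muscle layer) and is not smoothed.
    """
    if r_v <= 0:
        raise ValueError("lumen radius must be positive")
    h = max(1.0, 1.0 + 0.15 * (r_v - 3.0))
    l_g = L_G_OVER_H_ES * h
    if r_v >= 3.0:
        r_o = 1.3 * r_v + 1.5
    else:
        r_o = 1.15 * r_v + 0.95
    return SheathGeometry(h_ES_um=h, l_g_um=l_g, r_o_um=r_o)
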