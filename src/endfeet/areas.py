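"""Vessel-radius → endfoot-area relations and gap-fraction fits.

Two empirical ingredients connect vessel caliber to sheath geometry:

1. *Area relations* ``A(r_o)``: the mean endfoot area as a function of the
   outer sheath radius, quadratic for arterial vessels and linear for
   venous vessels.  The published relations live in a figure; the defaults
   here are anchored surrogates fitted through the printed anchor points
   (2.9 µm, 50 µm²) shared by both kinds, (15 µm, 490 µm²) arterial and
   (15 µm, 110 µm²) venous, and can be overridden by users who re-digitize
   the source data.

2. *Gap-fraction fits* ``phi(r_o) = c1*exp(-c2*r_o) + c3``: exponential
   summaries of the simulated gap area fraction at gap width 20 nm,

   - arterial: ``0.00704*exp(-0.1668*r_o) + 0.00124``, r_o in [2.5, 15] µm,
   - venous:   ``0.00468*exp(-0.0716*r_o) + 0.00226``, r_o in [2.5, 20] µm,

   with r_o in micrometres.  ``fit_gap_fraction_model`` re-derives such fits
   from simulated (r_o, phi_g) samples.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AreaRelation",
    "GapFractionFit",
    "ARTERIAL_AREA",
    "VENOUS_AREA",
    "ARTERIAL_GAP_FIT",
    "VENOUS_GAP_FIT",
    "MEASURED_CAPILLARY_ANCHOR",
    "mean_endfoot_area",
    "eval_gap_fraction_fit",
    "fit_gap_fraction_model",
]

#: Capillary anchor of the *uncorrected* (projected, as-imaged) area scale:
#: a (r_o µm, area µm²) pair used by the projection-correction tests.
MEASURED_CAPILLARY_ANCHOR = (2.9, 25.0)


@dataclass(frozen=True)
class AreaRelation:
    """Mean endfoot area as a polynomial in the outer sheath radius r_o.

    ``coefficients`` are highest-degree-first (numpy polyval order), in µm²
    for r_o in µm.  ``corrected`` distinguishes the projection-corrected
    area scale from the raw 2-D-measured one.
    """

    vessel_kind: str                 # "arterial" | "venous"
    form: str                        # "quadratic" | "linear"
    coefficients: tuple
    valid_radius_range: tuple = (2.5, 15.0)
    corrected: bool = True

    def __call__(self, r_o, extrapolate: bool = False):
        return mean_endfoot_area(r_o, self, extrapolate=extrapolate)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = list(self.coefficients)
        d["valid_radius_range"] = list(self.valid_radius_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AreaRelation":
        return cls(
            vessel_kind=d["vessel_kind"],
            form=d["form"],
            coefficients=tuple(d["coefficients"]),
            valid_radius_range=tuple(d["valid_radius_range"]),
            corrected=bool(d.get("corrected", True)),
        )


def _arterial_from_anchors(r1, a1, r2, a2) -> tuple:
    # quadratic with zero linear term through two anchors
    c2 = (a2 - a1) / (r2**2 - r1**2)
    c0 = a1 - c2 * r1**2
    return (c2, 0.0, c0)


def _venous_from_anchors(r1, a1, r2, a2) -> tuple:
    c1 = (a2 - a1) / (r2 - r1)
    c0 = a1 - c1 * r1
    return (c1, c0)


#: Corrected arterial relation, A(r_o) = 2.0315*r_o^2 + 32.915 µm².
ARTERIAL_AREA = AreaRelation(
    vessel_kind="arterial",
    form="quadratic",
    coefficients=_arterial_from_anchors(2.9, 50.0, 15.0, 490.0),
    valid_radius_range=(2.5, 15.0),
    corrected=True,
)

#: Corrected venous relation, A(r_o) = 4.9587*r_o + 35.620 µm².
VENOUS_AREA = AreaRelation(
    vessel_kind="venous",
    form="linear",
    coefficients=_venous_from_anchors(2.9, 50.0, 15.0, 110.0),
    valid_radius_range=(2.5, 20.0),
    corrected=True,
)


def mean_endfoot_area(r_o, relation: AreaRelation, extrapolate: bool = False):
    """Evaluate the stored area relation at radius ``r_o`` (µm → µm²).

    Out-of-range radii raise unless ``extrapolate=True`` is passed
    explicitly.
    """
    r = np.asarray(r_o, dtype=float)
    lo, hi = relation.valid_radius_range
    if not extrapolate and (np.any(r < lo) or np.any(r > hi)):
        raise ValueError(
            f"r_o outside the valid range [{lo}, {hi}] µm of the "
            f"{relation.vessel_kind} relation (pass extrapolate=True to override)"
        )
    val = np.polyval(relation.coefficients, r)
    return float(val) if np.isscalar(r_o) else val


@dataclass(frozen=True)
class GapFractionFit:
    """Exponential gap-fraction summary ``phi(r_o) = c1*exp(-c2*r_o) + c3``."""

    c1: float
    c2: float
    c3: float
    vessel_kind: str = ""
    valid_radius_range: tuple = (2.5, 15.0)
    residual_norm: float = 0.0

    def __call__(self, r_o, extrapolate: bool = False):
        return eval_gap_fraction_fit(r_o, self, extrapolate=extrapolate)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["valid_radius_range"] = list(self.valid_radius_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GapFractionFit":
        d = dict(d)
        d["valid_radius_range"] = tuple(d["valid_radius_range"])
        return cls(**d)


ARTERIAL_GAP_FIT = GapFractionFit(
    c1=0.00704, c2=0.1668, c3=0.00124,
    vessel_kind="arterial", valid_radius_range=(2.5, 15.0),
)

VENOUS_GAP_FIT = GapFractionFit(
    c1=0.00468, c2=0.0716, c3=0.00226,
    vessel_kind="venous", valid_radius_range=(2.5, 20.0),
)


def eval_gap_fraction_fit(r_o, fit: GapFractionFit, extrapolate: bool = False):
    """Evaluate ``c1*exp(-c2*r_o) + c3`` with range checking (µm in)."""
    r = np.asarray(r_o, dtype=float)
    lo, hi = fit.valid_radius_range
    if not extrapolate and (np.any(r < lo) or np.any(r > hi)):
        raise ValueError(
            f"r_o outside the fit range [{lo}, {hi}] µm (pass extrapolate=True)"
        )
    val = fit.c1 * np.exp(-fit.c2 * r) + fit.c3
    return float(val) if np.isscalar(r_o) else val


def fit_gap_fraction_model(r_o, phi_g, vessel_kind: str = "") -> GapFractionFit:
    """Least-squares fit of ``c1*exp(-c2*r) + c3`` to (r_o, phi_g) samples.

    Needs at least four distinct radii; raises on non-convergence.
    """
    r = np.asarray(r_o, dtype=float).ravel()
    phi = np.asarray(phi_g, dtype=float).ravel()
    if r.shape != phi.shape:
        raise ValueError("r_o and phi_g must have matching shapes")
    if len(np.unique(r)) < 4:
        raise ValueError("need samples at >= 4 distinct radii")

    def model(x, c1, c2, c3):
        return c1 * np.exp(-c2 * x) + c3

    c3_0 = float(phi[np.argmax(r)])
    c1_0 = max(float(phi[np.argmin(r)]) - c3_0, 1e-5)
    p0 = (c1_0, 0.15, max(c3_0, 1e-5))
    try:
        popt, _ = curve_fit(model, r, phi, p0=p0, maxfev=20_000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"exponential gap-fraction fit did not converge: {exc}")
    resid = float(np.linalg.norm(model(r, *popt) - phi))
    return GapFractionFit(
        c1=float(popt[0]), c2=float(popt[1]), c3=float(popt[2]),
        vessel_kind=vessel_kind,
        valid_radius_range=(float(r.min()), float(r.max())),
        residual_norm=resid,
    )
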