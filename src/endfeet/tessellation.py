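"""Periodic Voronoi tessellations of the endfoot sheath and gap metrics.

The sheath is tiled by the Voronoi cells of a (hard-core) point pattern on
the doubly periodic unrolled cylinder.  Cell bisector edges mark the
inter-endfoot gaps.  From the tessellation we derive

* ``phi_g = d_g * l_sigma / (2*pi*r_o*L)`` — the gap area fraction, where
  ``l_sigma`` is the total bisector edge length and ``d_g`` the gap width;
* ``gaps/ring = l_perp / L`` — the expected number of gaps crossed by a
  circular cross-sectional cut, where ``l_perp`` is the total edge length
  after projecting every edge onto the axial direction;
* ``phi_perp = d_g * l_perp / (2*pi*r_o*L)`` — the reduced gap area
  fraction implied by cross-sectional gap counts alone.

The periodic Voronoi diagram is built by replicating the point pattern on a
3x3 tiling of the fundamental domain and reading off the cells of the
central copy; each bisector is counted once per period (edges between a
central and a ghost generator carry weight 1/2, their periodic twin carries
the other half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi
from scipy import stats

from .surface import (
    DEFAULT_CELLS_PER_REALIZATION,
    DEFAULT_HARDCORE_FACTOR,
    SeedPoints,
    SurfaceDomain,
    domain_for_mean_area,
    sample_hardcore_points,
)

__all__ = [
    "EndfootTessellation",
    "SheathMetrics",
    "DistributionFits",
    "build_periodic_voronoi",
    "tessellation_metrics",
    "sheath_metrics",
    "fit_distributions",
    "hexagonal_gap_fraction",
    "cells_to_cylinder",
]

_AREA_RTOL = 1e-9


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class EndfootTessellation:
    """Voronoi tessellation of one realization of the endfoot sheath.

    ``cells[i]`` holds the polygon vertices of cell *i* in unrolled-plane
    coordinates continuous around its generator (vertices may leave the
    fundamental rectangle; the periodic wrap is implicit).  Edge arrays list
    every bisector touching the central copy with a weight of 1/2 per
    central endpoint so that summing ``weight * length`` counts each unique
    periodic bisector exactly once.
    """

    domain: SurfaceDomain
    points: np.ndarray          # (n, 2) generators
    cells: list                 # list of (k, 2) vertex arrays
    areas: np.ndarray           # (n,) cell areas, µm²
    edge_lengths: np.ndarray    # (m,) bisector lengths, µm
    edge_axial_extents: np.ndarray  # (m,) |Δz| of each bisector, µm
    edge_weights: np.ndarray    # (m,) 0.5 or 1.0 multiplicities

    @property
    def n_cells(self) -> int:
        return len(self.areas)

    @property
    def l_sigma(self) -> float:
        """Total bisector edge length per period (µm)."""
        return float(np.sum(self.edge_weights * self.edge_lengths))

    @property
    def l_perp(self) -> float:
        """Total axially projected bisector edge length per period (µm)."""
        return float(np.sum(self.edge_weights * self.edge_axial_extents))


def build_periodic_voronoi(
    seeds: SeedPoints | np.ndarray,
    domain: SurfaceDomain | None = None,
) -> EndfootTessellation:
    """Voronoi tessellation of a point set on the doubly periodic domain.

    Accepts either a :class:`~endfeet.surface.SeedPoints` object or a raw
    ``(n, 2)`` array together with ``domain``.  Cells of the central copy
    tile the fundamental rectangle; their areas sum to the domain area to
    relative precision ``1e-9``.
    """
    if isinstance(seeds, SeedPoints):
        pts = np.asarray(seeds.points, dtype=float)
        domain = seeds.domain
    else:
        pts = np.asarray(seeds, dtype=float)
        if domain is None:
            raise ValueError("domain required when passing a raw point array")
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("need an (n, 2) array with n >= 1")
    n = len(pts)

    # Coincident generators would make the diagram ill-defined; the
    # hard-core process excludes them upstream, but guard raw input too.
    rounded = np.round(pts, 9)
    if len(np.unique(rounded, axis=0)) != n:
        raise ValueError("coincident generator points")

    w, h = domain.width, domain.L
    offsets = [(0.0, 0.0)] + [
        (i * w, j * h)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        if (i, j) != (0, 0)
    ]
    tiled = np.concatenate([pts + np.asarray(off) for off in offsets])
    vor = Voronoi(tiled)

    cells: list[np.ndarray] = []
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError(
                "unbounded central Voronoi cell; cell extent exceeds one period"
            )
        poly = vor.vertices[region]
        cells.append(poly)
        areas[i] = _shoelace(poly)

    total = areas.sum()
    if abs(total - domain.area) > max(_AREA_RTOL * domain.area, 1e-12):
        raise RuntimeError(
            f"cells do not tile the domain: sum {total:.12g} vs {domain.area:.12g}"
        )

    lengths, extents, weights = [], [], []
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in rv:
            continue
        mult = int(p < n) + int(q < n)
        if mult == 0:
            continue
        a, b = vor.vertices[rv[0]], vor.vertices[rv[1]]
        seg = b - a
        length = float(np.hypot(seg[0], seg[1]))
        if length == 0.0:
            continue
        lengths.append(length)
        extents.append(abs(float(seg[1])))
        weights.append(0.5 * mult)

    return EndfootTessellation(
        domain=domain,
        points=pts,
        cells=cells,
        areas=areas,
        edge_lengths=np.asarray(lengths),
        edge_axial_extents=np.asarray(extents),
        edge_weights=np.asarray(weights),
    )


@dataclass(frozen=True)
class SheathMetrics:
    """Gap metrics of an ensemble of sheath realizations.

    Scalar fields are means over realizations; ``*_samples`` arrays keep
    the per-realization values and the pooled per-cell areas.
    """

    r_o: float                 # µm
    d_g: float                 # gap width, nm
    phi_g: float               # mean gap area fraction
    phi_perp: float            # mean reduced (projected) gap area fraction
    gaps_per_ring: float       # mean cross-sectional gap count
    mean_area: float           # mean cell area, µm²
    area_samples: np.ndarray   # pooled per-cell areas, µm²
    phi_samples: np.ndarray    # per-realization phi_g
    phi_perp_samples: np.ndarray
    gaps_samples: np.ndarray
    n_realizations: int
    seed: int | None = None


def tessellation_metrics(tess: EndfootTessellation, d_g_nm: float = 20.0) -> tuple[float, float, float]:
    """``(phi_g, phi_perp, gaps_per_ring)`` of a single tessellation."""
    if d_g_nm <= 0:
        raise ValueError("gap width must be positive")
    d_um = d_g_nm * 1e-3
    area = tess.domain.area
    return (
        d_um * tess.l_sigma / area,
        d_um * tess.l_perp / area,
        tess.l_perp / tess.domain.L,
    )


def sheath_metrics(
    r_o: float,
    mean_area: float,
    d_g_nm: float = 20.0,
    n_realizations: int = 1,
    seed: int | None = 0,
    n_cells: int = DEFAULT_CELLS_PER_REALIZATION,
    hardcore_factor: float = DEFAULT_HARDCORE_FACTOR,
) -> SheathMetrics:
    """Ensemble gap metrics for a vessel of sheath radius ``r_o``.

    Generates ``n_realizations`` independent hard-core Voronoi tessellations
    (realization *i* uses RNG seed ``seed + i``) on a cylinder of radius
    ``r_o`` whose axial length is chosen for ``n_cells`` expected endfeet of
    the requested mean area, and averages the gap metrics.

    Raises if the gap width is not small against the typical cell diameter
    (the thin-gap model assumes gap area fractions well below one).
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if d_g_nm <= 0:
        raise ValueError("gap width must be positive")
    if d_g_nm * 1e-3 >= np.sqrt(mean_area):
        raise ValueError(
            "gap width is of the order of the cell diameter; the thin-gap "
            "model (phi_g << 1) does not apply"
        )
    domain = domain_for_mean_area(r_o, mean_area, n_cells=n_cells)
    rho = 1.0 / mean_area

    phis = np.empty(n_realizations)
    phps = np.empty(n_realizations)
    gaps = np.empty(n_realizations)
    pooled: list[np.ndarray] = []
    base = 0 if seed is None else int(seed)
    for i in range(n_realizations):
        pts = sample_hardcore_points(
            domain, rho, seed=base + i, hardcore_factor=hardcore_factor
        )
        tess = build_periodic_voronoi(pts)
        phis[i], phps[i], gaps[i] = tessellation_metrics(tess, d_g_nm)
        pooled.append(tess.areas)

    areas = np.concatenate(pooled)
    return SheathMetrics(
        r_o=r_o,
        d_g=d_g_nm,
        phi_g=float(phis.mean()),
        phi_perp=float(phps.mean()),
        gaps_per_ring=float(gaps.mean()),
        mean_area=float(areas.mean()),
        area_samples=areas,
        phi_samples=phis,
        phi_perp_samples=phps,
        gaps_samples=gaps,
        n_realizations=n_realizations,
        seed=seed,
    )


@dataclass(frozen=True)
class DistributionFits:
    """Parametric fits to ensemble metrics: Gamma for per-cell areas,
    normal for the per-realization gap area fraction."""

    area_shape: float
    area_scale: float   # µm²
    phi_mean: float
    phi_sd: float

    @property
    def area_mean(self) -> float:
        return self.area_shape * self.area_scale


def fit_distributions(metrics: SheathMetrics) -> DistributionFits:
    """Maximum-likelihood Gamma fit to pooled cell areas and normal fit to
    the per-realization gap area fractions."""
    areas = metrics.area_samples
    phis = metrics.phi_samples
    if len(areas) < 100:
        raise ValueError("need at least 100 area samples")
    if len(phis) < 20:
        raise ValueError("need at least 20 phi_g samples")
    if np.ptp(areas) == 0 or np.ptp(phis) == 0:
        raise ValueError("zero-variance samples")
    shape, loc, scale = stats.gamma.fit(areas, floc=0.0)
    mu, sd = stats.norm.fit(phis)
    return DistributionFits(
        area_shape=float(shape),
        area_scale=float(scale),
        phi_mean=float(mu),
        phi_sd=float(sd),
    )


def hexagonal_gap_fraction(mean_area_um2: float, d_g_nm: float = 20.0) -> float:
    """Gap area fraction of a regular hexagonal tiling, in closed form.

    A regular hexagon of area A has side ``s = sqrt(2A/(3*sqrt(3)))`` and
    contributes half its perimeter, ``3s``, of bisector edge per cell, so
    ``phi = d * 3 s / A = d * sqrt(2*sqrt(3)) / sqrt(A)``.
    """
    if mean_area_um2 <= 0 or d_g_nm <= 0:
        raise ValueError("area and gap width must be positive")
    d_um = d_g_nm * 1e-3
    return d_um * np.sqrt(2.0 * np.sqrt(3.0)) / np.sqrt(mean_area_um2)


def cells_to_cylinder(tess: EndfootTessellation) -> list:
    """Map cell polygons onto the 3-D cylinder surface for visualization.

    Returns one ``(k, 3)`` array per cell with coordinates
    ``(r_o*cos(theta), r_o*sin(theta), z)`` where ``theta = x / r_o``.
    """
    r = tess.domain.r_o
    out = []
    for poly in tess.cells:
        theta = poly[:, 0] / r
        out.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), poly[:, 1]]))
    return out
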