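"""Virtual 2-D measurement of endfoot areas and projection-error correction.

Published endfoot areas come from 2-D micrographs: the cylinder surface is
seen in orthographic projection, so (1) surface patches are foreshortened
towards the vessel silhouette and (2) the far half of the vessel is hidden.
Both effects shrink the apparent area, the more so the smaller the vessel
(endfeet wrap around thin capillaries).

This module re-enacts that measurement on simulated tessellations: cells
are mapped onto the cylinder, clipped to the visible half, orthographically
projected into the image plane, and their planar areas taken as the
"measured" areas.  Averaging over many realizations yields a monotone
``measured -> true`` area mapping per vessel radius, which inverts the bias
in published area data.

The exact measurement convention of the original analysis is not published;
the default here (visible half-cylinder, a cell is counted when its
generator lies on the visible arc, its hidden part is clipped away) is a
documented reconstruction and every element is a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box
from sklearn.isotonic import IsotonicRegression

from .surface import sample_hardcore_points, domain_for_mean_area
from .tessellation import EndfootTessellation, build_periodic_voronoi

__all__ = [
    "ProjectionConvention",
    "AreaCorrectionTable",
    "measured_cell_areas",
    "simulate_projected_measurement",
    "simulate_mean_measured_area",
    "build_area_correction",
    "correct_measured_area",
]


@dataclass(frozen=True)
class ProjectionConvention:
    """Measurement convention for the virtual projection.

    visible_arc : (theta_lo, theta_hi) with theta = x/r_o; the visible half
        of the circumference (must span exactly pi by default assumptions).
    inclusion_rule : "generator" (cell counted iff its generator is on the
        visible arc) or "centroid".
    clip : clip each included cell to the visible arc before projecting
        (if False, the full cell is projected, wrapping and all).
    densify_rel : maximum polygon segment length before projection, as a
        fraction of r_o (controls the chord-approximation error of the
        curved projection).
    """

    visible_arc: tuple = (0.0, np.pi)
    inclusion_rule: str = "generator"
    clip: bool = True
    densify_rel: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.visible_arc
        if not 0 < hi - lo <= np.pi + 1e-12:
            raise ValueError("visible arc must span (0, pi]")
        if self.inclusion_rule not in ("generator", "centroid"):
            raise ValueError("inclusion_rule must be 'generator' or 'centroid'")


DEFAULT_CONVENTION = ProjectionConvention()


def _projected_polygon_area(
    poly_xy: np.ndarray, r: float, theta_lo: float, theta_hi: float, conv: ProjectionConvention
) -> float:
    """Projected planar area of one cell polygon (unrolled coords, µm)."""
    shape = Polygon(poly_xy)
    width = 2.0 * np.pi * r
    x_lo, x_hi = r * theta_lo, r * theta_hi
    zmin, zmax = poly_xy[:, 1].min() - 1.0, poly_xy[:, 1].max() + 1.0
    total = 0.0
    for shift in (-width, 0.0, width):
        if conv.clip:
            b = box(x_lo + shift, zmin, x_hi + shift, zmax)
            if not shape.intersects(b):
                continue
            part = shape.intersection(b)
        else:
            part = shape if shift == 0.0 else None
            if part is None:
                continue
        if part.is_empty:
            continue
        geoms = getattr(part, "geoms", [part])
        for g in geoms:
            if g.area == 0.0:
                continue
            g = g.segmentize(conv.densify_rel * r)
            coords = np.asarray(g.exterior.coords)
            # orthographic image coordinate across the visible arc
            u = -r * np.cos(coords[:, 0] / r - theta_lo)
            z = coords[:, 1]
            total += 0.5 * abs(np.dot(u, np.roll(z, -1)) - np.dot(z, np.roll(u, -1)))
    return total


def measured_cell_areas(
    tess: EndfootTessellation, conv: ProjectionConvention = DEFAULT_CONVENTION
) -> np.ndarray:
    """Measured (projected) areas of the included cells of one realization."""
    r = tess.domain.r_o
    width = tess.domain.width
    theta_lo, theta_hi = conv.visible_arc

    if conv.inclusion_rule == "generator":
        ref_x = tess.points[:, 0]
    else:
        ref_x = np.array([poly[:, 0].mean() for poly in tess.cells])
    theta_ref = np.mod(ref_x, width) / r
    included = (theta_ref > theta_lo) & (theta_ref < theta_hi)
    if not included.any():
        raise ValueError("no cells included under this convention")

    out = []
    for i in np.nonzero(included)[0]:
        out.append(_projected_polygon_area(tess.cells[i], r, theta_lo, theta_hi, conv))
    return np.asarray(out)


def simulate_projected_measurement(
    tess: EndfootTessellation, conv: ProjectionConvention = DEFAULT_CONVENTION
) -> float:
    """Mean measured area (µm²) of one tessellation under the convention."""
    return float(measured_cell_areas(tess, conv).mean())


def simulate_mean_measured_area(
    r_o: float,
    true_mean_area: float,
    n_realizations: int = 50,
    seed: int = 0,
    n_cells: int = 200,
    conv: ProjectionConvention = DEFAULT_CONVENTION,
) -> tuple[float, float]:
    """Ensemble mean measured area and its standard error for a vessel of
    radius ``r_o`` whose true mean endfoot area is ``true_mean_area``."""
    vals = np.empty(n_realizations)
    domain = domain_for_mean_area(r_o, true_mean_area, n_cells=n_cells)
    for i in range(n_realizations):
        pts = sample_hardcore_points(domain, 1.0 / true_mean_area, seed=seed + i)
        tess = build_periodic_voronoi(pts)
        vals[i] = simulate_projected_measurement(tess, conv)
    se = float(vals.std(ddof=1) / np.sqrt(n_realizations)) if n_realizations > 1 else 0.0
    return float(vals.mean()), se


@dataclass(frozen=True)
class AreaCorrectionTable:
    """Tabulated measured -> true area mapping on an (r_o, area) grid.

    ``A_meas[i, j]`` is the simulated mean measured area for true mean area
    ``A_true[i, j]`` at radius ``r_o[i]`` (isotonic-smoothed in j so the map
    is invertible); ``se`` holds Monte-Carlo standard errors and ``n_real``
    the per-node realization count.
    """

    r_o: np.ndarray     # (nr,)
    A_true: np.ndarray  # (nr, na)
    A_meas: np.ndarray  # (nr, na)
    se: np.ndarray      # (nr, na)
    n_real: int
    convention: ProjectionConvention = DEFAULT_CONVENTION


#: Radius grid covering capillaries through large penetrating vessels (µm).
DEFAULT_RADIUS_GRID = (2.0, 2.9, 4.0, 6.0, 8.0, 10.0, 12.0, 15.0, 20.0)


def _default_area_levels(n_levels: int = 12) -> np.ndarray:
    return np.geomspace(15.0, 600.0, n_levels)


def build_area_correction(
    r_o_grid=DEFAULT_RADIUS_GRID,
    A_true_grid=None,
    n_realizations: int = 50,
    seed: int = 0,
    n_cells: int = 200,
    conv: ProjectionConvention = DEFAULT_CONVENTION,
) -> AreaCorrectionTable:
    """Monte-Carlo tabulation of the measured/true area relationship.

    ``A_true_grid`` may be a 1-D array of area levels shared by all radii or
    a ``(len(r_o_grid), n_levels)`` array.  Monte-Carlo noise that violates
    monotonicity of measured vs. true area is removed by isotonic
    regression; a violation far beyond the noise scale raises, since it
    indicates a broken convention.
    """
    r_grid = np.asarray(r_o_grid, dtype=float)
    if len(r_grid) < 3:
        raise ValueError("need at least 3 radii")
    if A_true_grid is None:
        A_true_grid = _default_area_levels()
    A_true = np.asarray(A_true_grid, dtype=float)
    if A_true.ndim == 1:
        if len(A_true) < 3:
            raise ValueError("need at least 3 area levels")
        A_true = np.broadcast_to(A_true, (len(r_grid), len(A_true))).copy()
    if not (np.all(np.diff(r_grid) > 0) and np.all(np.diff(A_true, axis=1) > 0)):
        raise ValueError("grids must be strictly increasing")

    nr, na = A_true.shape
    meas = np.empty((nr, na))
    se = np.empty((nr, na))
    for i, r in enumerate(r_grid):
        for j in range(na):
            meas[i, j], se[i, j] = simulate_mean_measured_area(
                r, A_true[i, j],
                n_realizations=n_realizations,
                seed=seed + 1000 * i + 10 * j,
                n_cells=n_cells,
                conv=conv,
            )
        raw = meas[i].copy()
        iso = IsotonicRegression(increasing=True)
        meas[i] = iso.fit_transform(A_true[i], raw)
        tol = 5.0 * max(se[i].max(), 1e-9)
        if np.max(np.abs(meas[i] - raw)) > tol:
            raise RuntimeError(
                f"non-monotone measured areas beyond noise at r_o={r}: "
                "projection convention is inconsistent"
            )
        # strictify plateaus so the map stays invertible
        meas[i] = np.maximum.accumulate(meas[i] + 1e-9 * np.arange(na))

    if np.any(meas > A_true + 5.0 * se + 1e-9):
        raise RuntimeError("measured area exceeds true area; projection bug")

    return AreaCorrectionTable(
        r_o=r_grid, A_true=A_true, A_meas=meas, se=se,
        n_real=n_realizations, convention=conv,
    )


def correct_measured_area(A_meas: float, r_o: float, table: AreaCorrectionTable) -> float:
    """Invert the tabulated projection bias: true mean area (µm²) for a
    measured mean area at radius ``r_o``.  Raises outside the table hull."""
    r_grid = table.r_o
    if not (r_grid[0] <= r_o <= r_grid[-1]):
        raise ValueError(f"r_o={r_o} outside table radius range")
    hi = int(np.searchsorted(r_grid, r_o, side="left"))
    hi = min(max(hi, 1), len(r_grid) - 1)
    lo = hi - 1

    def invert(i: int) -> float:
        row_m, row_t = table.A_meas[i], table.A_true[i]
        if not (row_m[0] <= A_meas <= row_m[-1]):
            raise ValueError(
                f"measured area {A_meas} outside table hull "
                f"[{row_m[0]:.3g}, {row_m[-1]:.3g}] at r_o={r_grid[i]}"
            )
        return float(np.interp(A_meas, row_m, row_t))

    t_lo, t_hi = invert(lo), invert(hi)
    if r_grid[hi] == r_grid[lo]:
        return t_lo
    w = (r_o - r_grid[lo]) / (r_grid[hi] - r_grid[lo])
    return (1.0 - w) * t_lo + w * t_hi
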