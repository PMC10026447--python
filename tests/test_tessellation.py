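import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endfeet.surface import SurfaceDomain, sample_hardcore_points
from endfeet.tessellation import (
    build_periodic_voronoi,
    fit_distributions,
    hexagonal_gap_fraction,
    sheath_metrics,
    tessellation_metrics,
    cells_to_cylinder,
)


def triangular_lattice(a: float, ncols: int, nrows: int):
    """Commensurate triangular lattice on the periodic rectangle; Voronoi
    cells are regular hexagons of area a**2 * sqrt(3)/2."""
    assert nrows % 2 == 0
    dy = a * np.sqrt(3) / 2
    pts = []
    for r in range(nrows):
        off = 0.0 if r % 2 == 0 else a / 2
        for c in range(ncols):
            pts.append((c * a + off, r * dy))
    dom = SurfaceDomain(r_o=ncols * a / (2 * np.pi), L=nrows * dy)
    return np.asarray(pts), dom


def test_single_point_covers_domain():
    dom = SurfaceDomain(r_o=3.0, L=40.0)
    tess = build_periodic_voronoi(np.array([[5.0, 7.0]]), dom)
    assert tess.n_cells == 1
    assert tess.areas[0] == pytest.approx(dom.area, rel=1e-12)
    # the cell boundary is the two seam circles: one circumference + one axial line
    assert tess.l_sigma == pytest.approx(dom.width + dom.L, rel=1e-9)


def test_two_antipodal_points_split_evenly():
    dom = SurfaceDomain(r_o=3.0, L=40.0)
    pts = np.array([[0.0, 0.0], [dom.width / 2, dom.L / 2]])
    tess = build_periodic_voronoi(pts, dom)
    assert tess.areas == pytest.approx([dom.area / 2] * 2, rel=1e-9)


def test_coincident_points_raise():
    dom = SurfaceDomain(r_o=3.0, L=40.0)
    with pytest.raises(ValueError, match="coincident"):
        build_periodic_voronoi(np.array([[1.0, 1.0], [1.0, 1.0]]), dom)


def test_area_conservation_and_edge_invariants():
    dom = SurfaceDomain(r_o=2.9, L=300.0)
    pts = sample_hardcore_points(dom, 1 / 50.0, seed=2)
    tess = build_periodic_voronoi(pts)
    assert tess.n_cells == len(pts)
    assert abs(tess.areas.sum() - dom.area) / dom.area < 1e-9
    assert np.all(tess.areas > 0)
    assert tess.l_perp <= tess.l_sigma
    # every bisector is shared by two cells: summed half-perimeters = l_sigma
    per = sum(
        np.sum(np.hypot(*(np.roll(poly, -1, axis=0) - poly).T)) for poly in tess.cells
    )
    assert tess.l_sigma == pytest.approx(0.5 * per, rel=1e-9)


def test_hexagonal_lattice_matches_closed_form():
    # regular hexagons of area 50 um^2: phi_g = d*sqrt(2*sqrt(3))/sqrt(A)
    A = 50.0
    a = np.sqrt(2 * A / np.sqrt(3))
    pts, dom = triangular_lattice(a, ncols=8, nrows=8)
    tess = build_periodic_voronoi(pts, dom)
    phi, _, _ = tessellation_metrics(tess, d_g_nm=20.0)
    expected = hexagonal_gap_fraction(A, 20.0)
    assert phi == pytest.approx(expected, rel=1e-4)  # 4 significant digits
    assert np.allclose(tess.areas, A, rtol=1e-9)


def test_scale_invariance():
    dom = SurfaceDomain(r_o=2.9, L=120.0)
    pts = sample_hardcore_points(dom, 1 / 50.0, seed=5)
    tess = build_periodic_voronoi(pts)
    k = 3.7
    dom_k = SurfaceDomain(r_o=2.9 * k, L=120.0 * k)
    tess_k = build_periodic_voronoi(pts.points * k, dom_k)
    assert tess_k.l_sigma == pytest.approx(k * tess.l_sigma, rel=1e-9)
    phi, _, _ = tessellation_metrics(tess, d_g_nm=20.0)
    phi_k, _, _ = tessellation_metrics(tess_k, d_g_nm=20.0 * k)
    assert phi_k == pytest.approx(phi, rel=1e-9)


def test_ensemble_metrics_definition_and_determinism():
    m = sheath_metrics(2.9, 50.0, d_g_nm=20.0, n_realizations=3, seed=21, n_cells=120)
    assert m.phi_perp <= m.phi_g
    assert 0 < m.phi_g < 1
    assert m.phi_g == pytest.approx(np.mean(m.phi_samples), rel=1e-12)
    assert m.gaps_per_ring == pytest.approx(np.mean(m.gaps_samples), rel=1e-12)
    m2 = sheath_metrics(2.9, 50.0, d_g_nm=20.0, n_realizations=3, seed=21, n_cells=120)
    assert m.phi_samples.tobytes() == m2.phi_samples.tobytes()
    assert m.area_samples.tobytes() == m2.area_samples.tobytes()


def test_ensemble_metrics_guards():
    with pytest.raises(ValueError):
        sheath_metrics(2.9, 50.0, n_realizations=0)
    with pytest.raises(ValueError, match="thin-gap"):
        # 8 um "gap" on 50 um^2 cells is no longer a thin gap
        sheath_metrics(2.9, 50.0, d_g_nm=8000.0, n_realizations=1)
    with pytest.raises(ValueError):
        sheath_metrics(2.9, 50.0, d_g_nm=-1.0, n_realizations=1)


def test_fit_distributions_mean_consistency(capillary_ensemble):
    fits = fit_distributions(capillary_ensemble)
    # Gamma MLE preserves the sample mean; both should sit near the 50 um^2 target
    assert fits.area_mean == pytest.approx(capillary_ensemble.mean_area, rel=1e-6)
    assert fits.area_mean == pytest.approx(50.0, rel=0.03)
    assert fits.phi_mean == pytest.approx(capillary_ensemble.phi_g, rel=1e-9)
    assert fits.phi_sd > 0


def test_fit_distributions_degenerate_inputs(capillary_ensemble):
    import dataclasses

    flat = dataclasses.replace(
        capillary_ensemble,
        area_samples=np.full(200, 50.0),
        phi_samples=np.full(30, 0.005),
    )
    with pytest.raises(ValueError, match="zero-variance"):
        fit_distributions(flat)
    tiny = dataclasses.replace(capillary_ensemble, area_samples=np.arange(10.0))
    with pytest.raises(ValueError):
        fit_distributions(tiny)


def test_cells_to_cylinder_radius():
    dom = SurfaceDomain(r_o=3.0, L=40.0)
    pts = sample_hardcore_points(dom, 1 / 30.0, seed=1)
    tess = build_periodic_voronoi(pts)
    xyz = cells_to_cylinder(tess)
    for poly in xyz:
        assert np.allclose(np.hypot(poly[:, 0], poly[:, 1]), 3.0, rtol=1e-12)


@settings(deadline=None, derandomize=True)
@given(A=st.floats(5.0, 800.0), k=st.floats(0.2, 5.0))
def test_hexagonal_gap_fraction_scaling(A, k):
    # phi depends only on d/sqrt(A): scaling lengths by k leaves it unchanged
    base = hexagonal_gap_fraction(A, 20.0)
    assert hexagonal_gap_fraction(A * k**2, 20.0 * k) == pytest.approx(base, rel=1e-12)
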