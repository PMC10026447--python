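import numpy as np
import pandas as pd
import pytest

from endfeet.network import (
    NetworkParams,
    VascularNetwork,
    ViscosityConfig,
    apparent_viscosity,
    assign_transport_coefficients,
    classify_segments,
    endfoot_counts,
    flow_imbalance,
    generate_synthetic_network,
    relative_apparent_viscosity,
    segment_categories,
    simplify_network,
    solve_pressures,
    summarize_layers,
)


# ----------------------------------------------------------------- fixture

def test_generator_is_deterministic():
    a = generate_synthetic_network(seed=3)
    b = generate_synthetic_network(seed=3)
    assert a.node_xyz.tobytes() == b.node_xyz.tobytes()
    assert a.r_v.tobytes() == b.r_v.tobytes()
    assert generate_synthetic_network(seed=4).node_xyz.tobytes() != a.node_xyz.tobytes()


def test_fixture_statistics(fixture_network, fixture_segment_table):
    net, tab = fixture_network, fixture_segment_table
    assert net.is_connected()
    assert np.ptp(net.node_xyz[:, 2]) >= 1000.0  # full cortical depth
    # surface-to-volume ratio of order 1e4 m^2/m^3
    sv = tab["S_m2"].sum() / (net.bounding_box_volume * 1e-18)
    assert 0.5e4 < sv < 3e4
    # capillaries carry most of the exchange surface
    cats = tab["category"].to_numpy()
    s_cap = tab.loc[cats == "C", "S_m2"].sum()
    s_other = tab.loc[cats != "C", "S_m2"].sum()
    assert s_cap / s_other >= 5.0
    # radii respect the class conventions
    assert np.all(net.r_v > 0)
    assert net.r_v.max() <= 15.0


def test_generator_rejects_degenerate_params():
    with pytest.raises(ValueError):
        generate_synthetic_network(NetworkParams(nx=1, ny=1))
    with pytest.raises(ValueError):
        generate_synthetic_network(NetworkParams(n_arterioles=0, n_venules=0))


# ------------------------------------------------------- polyline simplify

def test_douglas_peucker_drops_subradius_jitter():
    net = VascularNetwork(
        node_xyz=np.array([[0.0, 0, 0], [100.0, 0, 0]]),
        segments=np.array([[0, 1]]),
        r_v=np.array([3.0]),
        polylines=[np.array([[0, 0, 0], [50, 1.0, 0], [100, 0, 0]], dtype=float)],
    )
    out = simplify_network(net)
    assert len(out.polylines[0]) == 2  # 1 um excursion < 3 um tolerance


def test_douglas_peucker_keeps_large_excursions_and_is_idempotent():
    poly = np.array([[0, 0, 0], [25, 8.0, 0], [50, -8.0, 0], [100, 0, 0]], dtype=float)
    net = VascularNetwork(
        node_xyz=np.array([[0.0, 0, 0], [100.0, 0, 0]]),
        segments=np.array([[0, 1]]),
        r_v=np.array([3.0]),
        polylines=[poly],
    )
    once = simplify_network(net)
    assert len(once.polylines[0]) == 4  # 8 um zigzag > 3 um tolerance
    twice = simplify_network(once)
    assert np.array_equal(once.polylines[0], twice.polylines[0])
    # endpoints always preserved
    assert np.array_equal(once.polylines[0][[0, -1]], poly[[0, -1]])


def test_simplification_shortens_towards_chord(fixture_network):
    raw = generate_synthetic_network(seed=7)
    assert np.all(fixture_network.lengths <= raw.lengths + 1e-9)


# ---------------------------------------------------------------- rheology

def test_viscosity_plasma_limit_and_scaling():
    assert relative_apparent_viscosity(10.0, hematocrit=0.0) == 1.0
    cfg = ViscosityConfig()
    assert (cfg.reference_rbc_volume_fl / cfg.rbc_volume_fl) ** (1 / 3) == pytest.approx(
        1.187, abs=2e-3
    )
    # capillary-scale blood is several times more viscous than plasma
    assert relative_apparent_viscosity(6.0, hematocrit=0.45) > 2.0
    with pytest.raises(ValueError):
        relative_apparent_viscosity(5.0, hematocrit=1.2)


def test_viscosity_constant_fallback():
    cfg = ViscosityConfig(mode="constant", constant_mu=1.0e-3)
    assert apparent_viscosity(3.0, config=cfg) == 1.0e-3
    assert apparent_viscosity(300.0, config=cfg) == 1.0e-3
    with pytest.raises(ValueError):
        apparent_viscosity(3.0, config=ViscosityConfig(mode="magic"))


# -------------------------------------------------------------------- flow

def _two_node_net(r_v=3.0, length=100.0):
    return VascularNetwork(
        node_xyz=np.array([[0.0, 0, 0], [length, 0, 0]]),
        segments=np.array([[0, 1]]),
        r_v=np.array([r_v]),
        bc_pressure={0: 100.0, 1: 0.0},
    )


def test_single_segment_poiseuille_closed_form():
    net = _two_node_net()
    flow = solve_pressures(net, viscosity=ViscosityConfig(mode="constant", constant_mu=1e-3))
    q_expected = np.pi * (3e-6) ** 4 * 100.0 / (8 * 1e-3 * 100e-6)
    assert flow.segment_flow[0] == pytest.approx(q_expected, rel=1e-12)
    assert flow.segment_flow[0] == pytest.approx(3.18e-14, rel=1e-2)


def test_symmetric_junction_splits_flow_evenly():
    # Y junction: one inlet branch feeding two identical outlets
    net = VascularNetwork(
        node_xyz=np.array([[0.0, 0, 0], [100.0, 0, 0], [200.0, 50, 0], [200.0, -50, 0]]),
        segments=np.array([[0, 1], [1, 2], [1, 3]]),
        r_v=np.array([4.0, 3.0, 3.0]),
        bc_pressure={0: 100.0, 2: 0.0, 3: 0.0},
    )
    flow = solve_pressures(net, viscosity=ViscosityConfig(mode="constant"))
    assert flow.segment_flow[1] == pytest.approx(flow.segment_flow[2], rel=1e-12)
    assert flow.segment_flow[0] == pytest.approx(
        flow.segment_flow[1] + flow.segment_flow[2], rel=1e-12
    )


def test_equal_boundary_pressures_give_no_flow(fixture_network):
    bcs = {k: 5000.0 for k in fixture_network.bc_pressure}
    flow = solve_pressures(fixture_network, bc_pressure=bcs)
    assert np.allclose(flow.segment_flow, 0.0, atol=1e-20)
    assert np.allclose(flow.node_pressure, 5000.0)


def test_flow_conservation_on_fixture(fixture_network, fixture_flow):
    assert flow_imbalance(fixture_network, fixture_flow) < 1e-8
    p = fixture_flow.node_pressure
    bc_vals = list(fixture_flow.bc_pressure.values())
    assert p.min() >= min(bc_vals) - 1e-9 and p.max() <= max(bc_vals) + 1e-9


def test_solver_guards():
    net = _two_node_net()
    with pytest.raises(ValueError):
        solve_pressures(net, bc_pressure={0: 100.0})


# ---------------------------------------------------------- classification

def test_linear_chain_classification_splits_at_midpoint():
    n = 11
    xyz = np.column_stack([np.linspace(0, 1000, n), np.zeros(n), np.zeros(n)])
    net = VascularNetwork(
        node_xyz=xyz,
        segments=np.column_stack([np.arange(n - 1), np.arange(1, n)]),
        r_v=np.full(n - 1, 2.0),
        bc_pressure={0: 100.0, n - 1: 0.0},
    )
    flow = solve_pressures(net, viscosity=ViscosityConfig(mode="constant"))
    labels = classify_segments(net, flow)
    assert list(labels[:5]) == ["arterial"] * 5
    assert list(labels[5:]) == ["venous"] * 5


def test_uniform_pressure_is_all_venous():
    # the rule is a strict "exceeds": ties go venous
    net = _two_node_net()
    flow = solve_pressures(net, bc_pressure={0: 50.0, 1: 50.0})
    assert list(classify_segments(net, flow)) == ["venous"]


def test_fixture_trunks_follow_boundary_conditions(fixture_network, fixture_labels):
    net = fixture_network
    # segments adjacent to inlet/outlet roots inherit the expected side
    for node, p in net.bc_pressure.items():
        touching = np.nonzero((net.segments == node).any(axis=1))[0]
        want = "arterial" if p == max(net.bc_pressure.values()) else "venous"
        assert set(fixture_labels[touching]) == {want}


def test_classification_needs_small_vessels():
    net = _two_node_net(r_v=10.0)
    flow = solve_pressures(net)
    with pytest.raises(ValueError):
        classify_segments(net, flow)


# ------------------------------------------------------- layers and counts

def test_segment_categories(fixture_network, fixture_labels):
    cats = segment_categories(fixture_network, fixture_labels)
    assert set(cats) <= {"A", "V", "C"}
    assert np.all((fixture_network.r_v < 3.0) == (cats == "C"))


def test_layer_capacities_add_up(fixture_network, fixture_segment_table):
    layers, totals = summarize_layers(fixture_network, fixture_segment_table)
    assert layers["S_m2"].sum() == pytest.approx(totals["S_m2"], rel=1e-12)
    assert layers["filtration_capacity"].sum() == pytest.approx(
        totals["filtration_capacity"], rel=1e-12
    )
    assert layers["diffusion_capacity"].sum() == pytest.approx(
        totals["diffusion_capacity"], rel=1e-12
    )
    # six layers, 200 um each except the last (100 um)
    spans = layers.drop_duplicates("layer")[["z_lo_um", "z_hi_um"]].to_numpy()
    widths = spans[:, 1] - spans[:, 0]
    assert list(widths) == [200.0] * 5 + [100.0]


def test_outer_volume_fraction_exceeds_lumen_fraction(fixture_network, fixture_segment_table):
    _, totals = summarize_layers(fixture_network, fixture_segment_table)
    assert totals["zeta_outer"] > totals["zeta_lumen"]
    assert totals["surface_to_volume"] > totals["lumen_surface_to_volume"]


def test_capillary_dominated_network_averages(fixture_network, fixture_segment_table):
    _, totals = summarize_layers(fixture_network, fixture_segment_table)
    tab = fixture_segment_table
    cap = tab[tab["category"] == "C"]
    cap_mean_lp = (cap["S_m2"] * cap["L_p"]).sum() / cap["S_m2"].sum()
    assert 0.5 < totals["mean_L_p"] / cap_mean_lp < 2.0
    # per-segment spread is large even though the average is capillary-like
    assert tab["L_p"].max() / tab["L_p"].min() > 5.0


def test_single_segment_layer_average_is_identity():
    net = VascularNetwork(
        node_xyz=np.array([[0.0, 0, 10.0], [0.0, 0, 110.0]]),
        segments=np.array([[0, 1]]),
        r_v=np.array([2.0]),
        bc_pressure={0: 100.0, 1: 0.0},
    )
    flow = solve_pressures(net)
    tab = assign_transport_coefficients(net, classify_segments(net, flow))
    layers, totals = summarize_layers(net, tab)
    row = layers[(layers["layer"] == 0) & (layers["S_m2"] > 0)].iloc[0]
    assert row["mean_L_p"] == pytest.approx(tab["L_p"].iloc[0], rel=1e-12)
    assert totals["mean_L_p"] == pytest.approx(tab["L_p"].iloc[0], rel=1e-12)


def test_endfoot_counts(fixture_network, fixture_segment_table):
    # direct division check: one category's count = sum(S / A(r_o))
    out = endfoot_counts(fixture_network, fixture_segment_table)
    assert out["total"] == pytest.approx(sum(out["by_category"].values()), rel=1e-12)
    assert out["by_category"]["C"] > out["by_category"]["A"]
    with pytest.raises(ValueError):
        endfoot_counts(fixture_network, fixture_segment_table, astrocyte_density_per_mm3=0.0)
    with_astro = endfoot_counts(
        fixture_network, fixture_segment_table, astrocyte_density_per_mm3=15_000.0
    )
    assert with_astro["endfeet_per_astrocyte"] > 0


def test_endfoot_count_simple_division():
    # 5000 um^2 of capillary surface at 50 um^2 per endfoot -> 100 endfeet
    length = 5000.0 / (2 * np.pi * sheath_r_o(2.0))
    net = VascularNetwork(
        node_xyz=np.array([[0.0, 0, 10.0], [0.0, 0, 10.0 + length]]),
        segments=np.array([[0, 1]]),
        r_v=np.array([2.0]),
        bc_pressure={0: 1.0, 1: 0.0},
    )
    flow = solve_pressures(net)
    tab = assign_transport_coefficients(net, classify_segments(net, flow))
    from endfeet.areas import AreaRelation

    flat = AreaRelation("venous", "linear", (0.0, 50.0), (0.1, 50.0))
    out = endfoot_counts(net, tab, arterial_area=flat, venous_area=flat)
    assert out["total"] == pytest.approx(100.0, rel=1e-6)


def sheath_r_o(r_v: float) -> float:
    from endfeet.permeability import sheath_geometry_from_lumen

    return sheath_geometry_from_lumen(r_v).r_o_um
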