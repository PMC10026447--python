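import numpy as np
import pytest

from endfeet import (
    generate_synthetic_network,
    sheath_metrics,
    simplify_network,
    solve_pressures,
    classify_segments,
    assign_transport_coefficients,
)


@pytest.fixture(scope="session")
def capillary_ensemble():
    """Modest capillary ensemble (r_o=2.9 µm, A=50 µm²) for unit tests."""
    return sheath_metrics(2.9, 50.0, d_g_nm=20.0, n_realizations=30, seed=11, n_cells=400)


@pytest.fixture(scope="session")
def fixture_network():
    net = generate_synthetic_network(seed=7)
    return simplify_network(net)


@pytest.fixture(scope="session")
def fixture_flow(fixture_network):
    return solve_pressures(fixture_network)


@pytest.fixture(scope="session")
def fixture_labels(fixture_network, fixture_flow):
    return classify_segments(fixture_network, fixture_flow)


@pytest.fixture(scope="session")
def fixture_segment_table(fixture_network, fixture_labels, fixture_flow):
    return assign_transport_coefficients(fixture_network, fixture_labels, fixture_flow)
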