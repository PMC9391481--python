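import pytest

from pasim import (
    ModuleLayout,
    build_weights,
    compute_adjoints,
    generate_patterns,
)


@pytest.fixture
def tiny_layout():
    """9 + 12 + 9 = 30 neurons on 3x3 / 3x4 / 3x3 grids."""
    return ModuleLayout(9, 12, 9, (3, 3), (3, 4), (3, 3))


@pytest.fixture
def tiny_ps(tiny_layout):
    return generate_patterns(tiny_layout, K=2, L=3, seed=7)


@pytest.fixture
def tiny_model(tiny_ps):
    w = build_weights(tiny_ps, compute_adjoints(tiny_ps))
    return tiny_ps, w


@pytest.fixture
def small_layout():
    """36 + 48 + 36 = 120 neurons; big enough for clean basins."""
    return ModuleLayout(36, 48, 36, (6, 6), (6, 8), (6, 6))


@pytest.fixture
def small_model(small_layout):
    ps = generate_patterns(small_layout, K=2, L=3, seed=11)
    w = build_weights(ps, compute_adjoints(ps))
    return ps, w


@pytest.fixture(scope="session")
def default_model():
    """The standard configuration: N = 3000, K = 11 cycles of period L = 10."""
    layout = ModuleLayout()
    ps = generate_patterns(layout, K=11, L=10, seed=1)
    adj = compute_adjoints(ps)
    w = build_weights(ps, adj)
    return ps, adj, w
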