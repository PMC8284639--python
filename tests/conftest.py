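import pytest

from gjcortex.network import (
    build_lattice,
    build_lgn_projection,
    build_pairwise_gj,
    build_recurrent_mask,
)


@pytest.fixture(scope="session")
def lattice_400():
    return build_lattice(400, p_inhibitory=0.2, rng_seed=7)


@pytest.fixture(scope="session")
def small_graph():
    """16-cell lattice with full wiring, for fast structural tests."""
    g = build_lattice(16, p_inhibitory=0.25, rng_seed=11)
    g.gj_edges = build_pairwise_gj(g, 0.5, rng_seed=3)
    g.recurrent_mask = build_recurrent_mask(g, None)
    g.lgn_map, g.lgn_weights_inh = build_lgn_projection(g, n_lgn=50, p_connect=0.5, rng_seed=5)
    g.validate()
    return g
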