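import pytest

import lincnet as ln

# Desk-scale study: same design (two groups x two timepoints, 12/group),
# scaled-down transcript counts so the whole suite stays fast.
SMALL_KW = dict(
    n_lnc=150, n_mrna=500,
    n_de_lnc={"6wk": (12, 8), "20wk": (30, 20)},
    n_de_mrna={"6wk": (10, 6), "20wk": (45, 30)},
    n_shared_de_lnc=(4, 3),
    n_hubs=3, hub_block_size=8,
    n_go_terms=15, n_pathway_terms=8, term_size_range=(5, 40),
)


@pytest.fixture(scope="session")
def small_config():
    return ln.SimulationConfig(**SMALL_KW, seed=101)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(catalog, study, truth, gene_sets) — treat as read-only."""
    return ln.simulate_study(small_config)
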