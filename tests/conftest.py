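import warnings

import pytest

from mitevol.simulate import SimulationConfig, generate

ZERO_RATES = {k: 0.0 for k in
              ("dcj", "sesqui", "a_insert", "a_delete", "b_insert", "b_delete")}


@pytest.fixture(autouse=True)
def _quiet_branch_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="negative branch length")
        yield


@pytest.fixture(scope="session")
def static_dataset():
    """A small simulated dataset with no gene-order evolution: six
    genomes, ten genes, six planted conserved elements."""
    cfg = SimulationConfig(seed=11, n_genes=10, n_leaves=6,
                           event_rates=dict(ZERO_RATES),
                           n_planted_hces=6, per_base_mutation_rate=0.02)
    return generate(cfg)


@pytest.fixture(scope="session")
def evolved_dataset():
    """Six genomes, twenty genes, one or two rearrangement/content
    events per branch."""
    cfg = SimulationConfig(
        seed=5, n_genes=20, n_leaves=6,
        event_rates={"dcj": 0.6, "sesqui": 0.2, "b_insert": 0.1,
                     "b_delete": 0.1, "a_insert": 0.0, "a_delete": 0.0},
        events_per_edge_range=(1, 2), n_planted_hces=0)
    return generate(cfg)
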