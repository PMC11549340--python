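import os

import pytest

from lncsynt.funnel import FunnelConfig
from lncsynt.pipeline import discover_simulated
from lncsynt.synthetic_data import GenomeSimParams, simulate_genome_pair

#: single suite-wide seed for every stochastic fixture
SEED = 0

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


@pytest.fixture(scope="session")
def toy_gff3():
    return os.path.join(DATA_DIR, "toy.gff3")


@pytest.fixture(scope="session")
def paper_shaped_pair():
    """Default 'paper-shaped' scenario: ~1200 genes, ~330 lncRNAs, three
    trait sets, 10 planted candidates, 3 decoys per criterion."""
    return simulate_genome_pair(GenomeSimParams(seed=SEED))


@pytest.fixture(scope="session")
def paper_shaped_result(paper_shaped_pair):
    return discover_simulated(paper_shaped_pair, config=FunnelConfig())


def small_params(seed, **overrides):
    """A fast, small simulation used in randomized oracle comparisons."""
    defaults = dict(
        seed=seed,
        n_chromosomes=4,
        genes_per_chromosome=30,
        trait_set_sizes={"heart": 25, "blood_vessels": 12, "endothelium": 6},
        n_planted_candidates=2,
        n_decoys_per_criterion=1,
    )
    defaults.update(overrides)
    return GenomeSimParams(**defaults)
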