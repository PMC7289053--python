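import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from syntegraph import simgenomes
from syntegraph.pipeline import DEFAULT_TREE, default_evolution_config
from syntegraph.simgenomes import EvolutionConfig, SpeciesTree


@pytest.fixture
def small_cfg():
    return EvolutionConfig(n_background_genes=10, n_chromosomes=2, seed=11)


@pytest.fixture
def four_leaf_tree():
    return SpeciesTree.from_newick(DEFAULT_TREE)


@pytest.fixture(scope="session")
def default_run():
    """One default-scenario simulation shared across tests."""
    cfg = default_evolution_config(seed=101)
    tree = SpeciesTree.from_newick(DEFAULT_TREE)
    genomes, log = simgenomes.evolve(tree, cfg)
    return cfg, tree, genomes, log
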