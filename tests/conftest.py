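import numpy as np
import pytest

from phylograft.simulate import SimConfig, make_toy_genome, simulate_gene_trees
from phylograft.species import SpeciesMap


@pytest.fixture(scope="session")
def smap():
    """Study-design species map: four query cichlids, human + zebrafish references."""
    return SpeciesMap()


@pytest.fixture(scope="session")
def lossfree_families():
    """200 loss-free simulated families on the 10-taxon fixture species tree."""
    return simulate_gene_trees(SimConfig(dup_rate=0.3, loss_rate=0.0, seed=11, n_families=200))


@pytest.fixture(scope="session")
def lossy_families():
    """200 simulated families with losses (the precision-only regime)."""
    return simulate_gene_trees(SimConfig(dup_rate=0.3, loss_rate=0.2, seed=12, n_families=200))


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """The ~20-gene toy genome fixture set, written once per session."""
    out = tmp_path_factory.mktemp("toy_genome")
    make_toy_genome(out, seed=0)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
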