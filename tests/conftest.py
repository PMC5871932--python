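import numpy as np
import pytest

from gsbreed import presets
from gsbreed.simulate import (
    build_trait_architecture,
    make_map,
    observe_markers,
    phenotype,
    simulate_founders,
)


@pytest.fixture(scope="session")
def small_map():
    return make_map(n_markers=200, n_linkage_groups=4, length_cm=100.0,
                    dominant_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def codominant_map():
    return make_map(n_markers=200, n_linkage_groups=4, length_cm=100.0,
                    dominant_fraction=0.0, seed=12)


@pytest.fixture(scope="session")
def founders(small_map):
    return simulate_founders(120, small_map, seed=21)


@pytest.fixture(scope="session")
def index_model():
    return presets.selection_index_model()


@pytest.fixture(scope="session")
def table_corr():
    return presets.target_architecture_corr()


@pytest.fixture(scope="session")
def small_arch(small_map):
    return build_trait_architecture(
        small_map,
        presets.target_architecture_corr().to_numpy(),
        h2=0.5,
        n_qtl=60,
        seed=31,
        trait_names=["seed_yield"] + presets.TRAIT_NAMES,
    )


@pytest.fixture(scope="session")
def trained_setup(codominant_map, small_arch):
    """Genotypes + phenotypes of one 120-plant population (codominant panel)."""
    pop = simulate_founders(120, codominant_map, seed=41)
    geno = observe_markers(pop, codominant_map, seed=42)
    phenos = phenotype(pop, small_arch, seed=43)
    return pop, geno, phenos
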