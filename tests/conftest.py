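import warnings

import numpy as np
import pytest

import phqtl

warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture(scope="session")
def haplo20():
    _, haplo = phqtl.simulate_genomes(20, n_chromosomes=2,
                                      markers_per_chromosome=25, seed=11)
    return haplo


@pytest.fixture(scope="session")
def loco20(haplo20):
    return phqtl.loco_grms(haplo20)


@pytest.fixture(scope="session")
def haplo58():
    _, haplo = phqtl.simulate_genomes(58, n_chromosomes=2,
                                      markers_per_chromosome=25, seed=13)
    return haplo


@pytest.fixture(scope="session")
def loco58(haplo58):
    return phqtl.loco_grms(haplo58)


@pytest.fixture(scope="session")
def small_study(haplo20):
    design = phqtl.MultiomicsDesign(
        n_proteins=30, n_local_pqtl=8, n_mech1=3, n_mech2=3,
        n_sex_protein=2, n_sex_phospho=2, n_single_peptide_phospho_parents=1)
    return phqtl.simulate_multiomics(haplo20, design, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
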