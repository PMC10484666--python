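import numpy as np
import pytest

from m6abind import synth


@pytest.fixture(scope="session")
def bli_dataset():
    """Default noisy biosensor dataset (5-320 nM doubling, triplicates, 1% noise)."""
    return synth.gen_bli_dataset(seed=20230628)


@pytest.fixture(scope="session")
def peak_pair():
    """Free/bound amide peak tables with a planted perturbed subset."""
    return synth.gen_peak_tables(seed=20230628)


@pytest.fixture(scope="session")
def genome_fixture():
    """Toy chromosome with 7 of 20 peaks planted on m6A sites."""
    return synth.gen_genome_fixture(n_peaks=20, n_sites=12,
                                    planted_overlap_count=7, seed=20230628)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
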