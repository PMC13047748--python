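import numpy as np
import pytest

from ptcascade.fit import fit_all_genes
from ptcascade.simulate import simulate_cascade


@pytest.fixture(scope="session")
def small_cascade():
    """60 genes x 150 cells, single sample, default noise/censoring."""
    return simulate_cascade(60, 150, seed=11)


@pytest.fixture(scope="session")
def small_fit(small_cascade):
    m, ords, truth = small_cascade
    fits, scaled = fit_all_genes(m, ords["s1"])
    return fits, scaled, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
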