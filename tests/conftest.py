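import numpy as np
import pytest

from poolscreen import synthetic_pool as sp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_catalog():
    """20 homozygous strains with well-separated tags."""
    return sp.make_catalog(20, seed=7)


@pytest.fixture
def mixed_catalog():
    """All three libraries; DAmP genes shadow the heterozygous ones."""
    return sp.make_catalog(12, 4, 4, seed=11)


@pytest.fixture
def three_strain_catalog():
    """The closed-form renormalization fixture: equal start, survivals
    (1.0, 0.25, 1.0) under the severe dose."""
    cat = sp.make_catalog(3, seed=3)
    cat[1].survival["H2O2_1.0mM"] = 0.25
    return cat


@pytest.fixture
def design():
    return sp.standard_design(pretreatment="NaCl")
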