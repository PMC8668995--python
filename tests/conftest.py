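import numpy as np
import pytest

from wee1kit import synthetic
from wee1kit.motif import builtin_wee1_catalog
from wee1kit.pairwise import ScoringScheme, blosum62


@pytest.fixture(scope="session")
def scheme():
    return blosum62()


@pytest.fixture(scope="session")
def small_scheme():
    """Cheap 4-letter-friendly scheme for brute-force comparisons."""
    return blosum62(gap_open=4.0, gap_extend=1.0)


@pytest.fixture(scope="session")
def catalog():
    return builtin_wee1_catalog()


@pytest.fixture(scope="session")
def wee1_reference():
    return synthetic.synthetic_reference_wee1()


@pytest.fixture(scope="session")
def study_family():
    return synthetic.synthetic_wee1_study_family()


@pytest.fixture(scope="session")
def site_positions(catalog):
    return tuple(p for s in catalog.sites for p in s.positions)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
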