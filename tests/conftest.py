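import numpy as np
import pytest

import motifstat as ms


@pytest.fixture(scope="session")
def splice_counts():
    """The 246 donor splice-site count matrix (17 sites)."""
    return ms.splice_site_counts()


@pytest.fixture(scope="session")
def splice_bg():
    """Intron-wide background (A=0.3279, C=0.1915, G=0.2043, U=0.2763)."""
    return ms.splice_site_background()


@pytest.fixture(scope="session")
def demo_states():
    """Published C0/C bookkeeping states of the Gibbs walk-through."""
    return ms.gibbs_demo_states()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture()
def small_seqs():
    return ms.SequenceSet.from_strings(
        ["ACGTACGTAC", "TTATCAGGAC", "CCCGGGTTTA"], ["s1", "s2", "s3"]
    )
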