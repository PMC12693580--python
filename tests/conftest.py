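import numpy as np
import pytest

import admixpgs as ap


@pytest.fixture(scope="session")
def small_cohort():
    """A small admixed cohort shared across read-only tests."""
    g = ap.sample_global_ancestry(300, seed=11)
    la = ap.sample_local_ancestry(g, 80, mode="independent", seed=12)
    freqs = ap.sample_ancestral_frequencies(80, seed=13)
    hap = ap.sample_haplotypes(la, freqs, seed=14)
    return dict(global_ancestry=g, la=la, freqs=freqs, hap=hap)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
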