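import numpy as np
import pytest

from bepipe import simkit


@pytest.fixture(scope="session")
def small_plasmid():
    """A compact screening plasmid (200-codon nCas9-like CDS, ~3.3 kb)."""
    return simkit.make_screen_plasmid(seed=7, cds_len_aa=200)


@pytest.fixture(scope="session")
def cargo():
    rng = np.random.default_rng(11)
    return simkit.random_dna(rng, 300)
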