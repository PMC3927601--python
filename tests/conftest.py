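import numpy as np
import pytest

from islandscout.genome_model import AnnotatedGenome, CircularInterval, Feature

BASES = np.array(list("ACGT"))


def random_dna(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(20250903)


@pytest.fixture
def toy_genome(rng):
    """10-kb random circular genome with three features."""
    seq = random_dna(rng, 10_000)
    feats = [
        Feature("TOY00010", "CDS", CircularInterval(501, 1700), "+",
                product="hypothetical protein"),
        Feature("TOY00020", "tRNA", CircularInterval(3001, 3076), "+",
                product="tRNA-Val", anticodon="CAC"),
        Feature("TOY00030", "CDS", CircularInterval(5001, 6200), "-",
                product="phage integrase"),
    ]
    return AnnotatedGenome(id="TOY1", sequence=seq, topology="circular",
                           features=feats, description="toy fixture genome")
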