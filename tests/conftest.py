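import numpy as np
import pytest

from omegakit.locus_model import DNA_BASES


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(DNA_BASES[b] for b in rng.integers(0, 4, size=n))


@pytest.fixture
def template_300() -> str:
    """A fixed random 300-nt locus template."""
    return random_dna(300, seed=991)


@pytest.fixture
def scaffold_120() -> str:
    """A fixed random 120-nt omegaRNA scaffold."""
    return random_dna(120, seed=992)
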