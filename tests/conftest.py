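import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20220119)


def random_composition(rng, max_counts=(60, 100, 20, 20, 3)):
    """Random peptide-scale elemental composition (up to C60 H100 N20 O20 S3)."""
    from midaflux.mida import ElementalComposition

    c, h, n, o, s = (int(rng.integers(0, m + 1)) for m in max_counts)
    if c + h + n + o + s == 0:
        c = 1
    return ElementalComposition(C=c, H=h, N=n, O=o, S=s)


def random_tryptic_sequence(rng, min_len=6, max_len=25):
    from midaflux.simulate import AMINO_ACIDS

    length = int(rng.integers(min_len, max_len))
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return body + rng.choice(["K", "R"])
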