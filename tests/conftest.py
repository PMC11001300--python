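import numpy as np
import pytest

from mamoscan import fixtures, pwmscan

# B. mori genome base composition used for genome-context p-values
BMORI_GC = 0.374


@pytest.fixture(scope="session")
def mamo_pwm():
    return fixtures.mamo_s_printed_pwm()


@pytest.fixture(scope="session")
def genome_background():
    gc = BMORI_GC
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@pytest.fixture
def rng():
    return np.random.default_rng(20240408)


def random_dna(rng, length, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(pwmscan.ALPHABET))[rng.choice(4, length, p=p)])
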