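import numpy as np
import pytest

from plastevo.synthetic_data import PlastomeSpec, generate_plastome, random_clock_tree


@pytest.fixture(scope="session")
def small_plastome():
    """A compact synthetic plastome (30/12/8 kb) with its ground truth."""
    spec = PlastomeSpec(lsc_len=30000, ir_len=12000, ssc_len=8000, seed=42)
    return generate_plastome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clock_tree6():
    return random_clock_tree(6, 0.05, seed=2)


def random_dna(rng, n, at=0.64):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), p=p, size=n))
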