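import numpy as np
import pytest

from mrkit import synthetic


@pytest.fixture
def table1():
    """The four BDNF-region instruments with schizophrenia outcomes."""
    return synthetic.table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20170119)


def random_harmonized(rng, n=10):
    """A random well-behaved instrument set for property checks."""
    from mrkit.summary_data import HarmonizedSet

    bx = rng.normal(0.1, 0.04, n)
    bx[np.abs(bx) < 1e-3] = 0.05
    return HarmonizedSet.from_arrays(
        [f"rs{i}" for i in range(n)],
        bx,
        rng.uniform(0.005, 0.02, n),
        rng.normal(0.02, 0.05, n),
        rng.uniform(0.008, 0.03, n),
    )
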