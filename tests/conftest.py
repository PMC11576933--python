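import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small two-resolution phantom cohort shared by pipeline tests."""
    from neoseg.phantom import make_cohort

    return make_cohort(12, resolutions=(0.5, 1.0), split_fractions=(0.5, 0.25, 0.25), seed=7)
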