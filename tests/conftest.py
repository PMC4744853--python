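import numpy as np
import pytest

from microevo import synthetic_clade as sc


@pytest.fixture(scope="session")
def default_clade():
    """The desk-scale study clade (290 core / 30 shared / 12+11+9 specific,
    ANI-calibrated branch rates, one GIm2d-like island in m2_6)."""
    return sc.generate_clade(sc.default_config(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
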