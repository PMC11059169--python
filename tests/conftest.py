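import numpy as np
import pytest

from nemalign import ModelParams, QTensorField, mdck_params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return mdck_params()


@pytest.fixture
def random_q_pair(rng):
    """Random small-amplitude Q^n, Q^m on an 8x8 periodic grid."""
    shape = (8, 8)
    qn = QTensorField(rng.normal(0, 0.3, shape), rng.normal(0, 0.3, shape))
    qm = QTensorField(rng.normal(0, 0.3, shape), rng.normal(0, 0.3, shape))
    return qn, qm
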