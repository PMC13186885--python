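import numpy as np
import pytest

from mistime.models import CosineParams, Glut4Params, GompertzParams, LinearParams, ParasiteParams

PARASITE_TRUTH = ParasiteParams(0.002, 0.531, 0.02, 0.323)
COSINE_TRUTH = CosineParams(3.0, 4.0)
LINEAR_TRUTH = LinearParams(0.0, 1.0)
GOMPERTZ_REF = GompertzParams(110.0, 0.08, 4000.0)
GLUT4_REF = Glut4Params(P0=0.1, k=0.1, M=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def parasite_truth():
    return PARASITE_TRUTH


@pytest.fixture
def cosine_truth():
    return COSINE_TRUTH
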