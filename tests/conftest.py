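import numpy as np
import pytest

from tendonscale.constitutive import FibrousMatrixParams
from tendonscale.recruitment import RecruitmentParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def recruit_params():
    """Reference slack-length population: mu 1 mm, sigma 0.1 mm, K_tot 10 N/mm."""
    return RecruitmentParams.from_total_stiffness(mu=1.0, sigma=0.1, K_tot=10.0)


@pytest.fixture
def matrix_params():
    """Reference fibrous matrix with a clear toe and stiffening regime."""
    return FibrousMatrixParams.from_youngs(E_b=1.0, E_f=30.0, lambda1=1.01,
                                           lambda2=1.04, n=5.0, m=10.0)
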