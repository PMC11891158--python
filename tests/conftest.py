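import numpy as np
import pytest

from radiosim import ModelParameters, presets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_grower():
    """Aggressive parameter set: doubles in ~1.5 days, cheap to simulate."""
    return ModelParameters(T_c=31, T_G0=50, T_N=10, T_A=5, N_LIMP=2,
                           R_A=1e-4, R_NDiff=0, R_ADiff=1e-4,
                           P_G0toG1=0.9, P_sleep=0.05, P_sym=0.9)


@pytest.fixture
def case0():
    return presets.case(0)


@pytest.fixture
def solution1():
    return presets.solution(1)
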