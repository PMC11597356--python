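import numpy as np
import pytest

from qsarnest.features import FeatureMatrix
from qsarnest.synthetic_data import SyntheticSpec, gen_regression_problem


@pytest.fixture(scope="session")
def strong_signal_problem():
    """n=300, p=50, 5 planted features, generative R*2 = 0.75."""
    spec = SyntheticSpec(n=300, p=50, k_informative=5, r_star2=0.75, seed=11)
    return gen_regression_problem(spec)


@pytest.fixture(scope="session")
def independent_problem():
    """Planted-truth problem with independent features (clean ground truth)."""
    spec = SyntheticSpec(
        n=300, p=50, k_informative=5, beta=(1,) * 5, noise_sd=0.5, r_star2=None,
        block_corr=0.0, seed=5,
    )
    return gen_regression_problem(spec)


@pytest.fixture
def small_binary_fm():
    rng = np.random.default_rng(3)
    values = rng.integers(0, 2, size=(12, 20)).astype(float)
    return FeatureMatrix(
        values=values, feature_names=[f"b{j}" for j in range(20)], feature_kind="binary"
    )
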