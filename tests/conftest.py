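import numpy as np
import pytest

from betaimt.betadist import FractionalSample, ThetaMP, sample_beta


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def theta_grid():
    """A small spread of parameter points covering skewed and symmetric laws."""
    return [
        ThetaMP(0.2, 40.0),
        ThetaMP(0.5, 20.0),
        ThetaMP(0.75, 120.0),
        ThetaMP(0.1, 3.0),
        ThetaMP(0.9, 8.0),
    ]


@pytest.fixture
def beta_sample(rng):
    """A moderate correctly specified sample."""
    return sample_beta(ThetaMP(0.3, 25.0), 200, rng)


def random_theta(rng):
    return ThetaMP(float(rng.uniform(0.08, 0.92)), float(np.exp(rng.uniform(0.5, 4.5))))


def random_sample(rng, theta, n=60) -> FractionalSample:
    return sample_beta(theta, n, rng)
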