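import numpy as np
import pytest

from rmstaug import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_dataset():
    """8 subjects, both arms, one covariate; events and censorings mixed."""
    return SurvivalDataset(
        time=[1.0, 2.0, 3.0, 4.5, 0.5, 2.5, 3.5, 5.0],
        event=[1, 0, 1, 1, 1, 1, 0, 1],
        arm=[1, 1, 1, 1, 0, 0, 0, 0],
        covariates=np.array([[0.3], [-1.2], [0.8], [2.0],
                             [-0.5], [1.1], [0.0], [-0.7]]),
        covariate_names=["cov_x"],
    )


def random_two_arm_dataset(rng, n=40, p=2, censor=True):
    """Small random dataset guaranteed to contain both arms and events."""
    while True:
        time = rng.exponential(2.0, n)
        cens = rng.uniform(0, 4.0, n) if censor else np.full(n, np.inf)
        event = (time <= cens).astype(int)
        x = np.minimum(time, cens)
        arm = (rng.random(n) < 0.5).astype(int)
        if 0 < arm.sum() < n and event[arm == 1].sum() and event[arm == 0].sum():
            break
    V = rng.standard_normal((n, p))
    return SurvivalDataset(time=x, event=event, arm=arm, covariates=V)
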