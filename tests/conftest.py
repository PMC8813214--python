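import numpy as np
import pytest

from plspline.data import SurvivalData
from plspline.simulate import SimulationSpec, simulate_dataset


def strip_covariates(data: SurvivalData) -> SurvivalData:
    """Same times/status with an empty covariate matrix."""
    return SurvivalData(data.time, data.status, np.empty((data.n, 0)))


def null_weibull_data(n: int, seed: int, horizon: float = 5.0) -> SurvivalData:
    """Weibull(0.1, 1.5) survival data with no covariate effects."""
    spec = SimulationSpec(
        n=n, p=1, true_beta=np.zeros(1), seed=seed, censor_horizon=horizon
    )
    return strip_covariates(simulate_dataset(spec))


@pytest.fixture(scope="session")
def weibull_data_2000() -> SurvivalData:
    return null_weibull_data(2000, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
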