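import numpy as np
import pytest

from spiralmix.data_model import CohortData
from spiralmix.priors import PriorConfig
from spiralmix.spiral_mcmc import GroupHyperparameters
from spiralmix.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A tiny deterministic 4-individual, 6-trial cohort."""
    t = np.arange(1, 7, dtype=float)
    scores = np.vstack([
        100 + 2 * t,
        98 + 1.5 * t,
        101 + 2 * np.minimum(t, 3) - 2.5 * np.maximum(t - 3, 0),
        100 + np.array([0.3, -0.2, 0.5, -0.4, 0.1, 0.0]),
    ])
    return CohortData(
        individual_ids=[1, 2, 3, 4],
        groups=["entity", "entity", "incremental", "incremental"],
        scores=scores,
    )


@pytest.fixture
def study_cohort():
    cohort, truth = generate_cohort(GeneratorConfig(seed=20240915))
    return cohort, truth


@pytest.fixture
def default_hypers():
    return GroupHyperparameters(
        mu_alpha=100.0, tau_alpha2=9.0,
        mu_beta1=np.array([2.0, 1.5]), tau_beta12=1.5,
        mu_beta2=np.array([-2.5, -2.0]), tau_beta22=2.0,
        sigma2=4.0, delta=np.array([0.5, -1.0]),
    )


@pytest.fixture
def tight_priors():
    """Moderately informative priors for fast, stable test chains."""
    return PriorConfig(
        mu_alpha=(100.0, 5.0), mu_beta=(1.0, 2.0),
        mu_beta1=(2.0, 1.0), mu_beta2=(-2.0, 1.0),
        sigma2=(3.0, 50.0), tau_alpha2=(3.0, 20.0),
        tau_beta2_baseline=(3.0, 2.0),
        tau_beta12=(3.0, 2.0), tau_beta22=(3.0, 2.0),
        c_delta=4.0,
    )
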