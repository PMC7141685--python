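import numpy as np
import pytest

from frdd import (
    CaptureRecaptureModel,
    CRPriorSet,
    DiscreteUniformPrior,
    LogNormalPrior,
    SimulationConfig,
    UniformPrior,
    simulate_survey,
)
from frdd.simulate import elicited_confinement_prior


@pytest.fixture(scope="session")
def survey():
    """One fixed synthetic village survey (120 owned dogs, 4 transects)."""
    return simulate_survey(SimulationConfig(n_owned=120, p_true=0.6, seed=42))


@pytest.fixture(scope="session")
def survey_priors(survey):
    """Priors matched to the generative truth of the ``survey`` fixture."""
    return CRPriorSet(
        recapture=UniformPrior(0.4, 0.8),
        confinement=elicited_confinement_prior(survey.config),
        ratio=LogNormalPrior(survey.config.ratio_mu, survey.config.ratio_tau),
        owned=DiscreteUniformPrior(survey.marking.n_collared, 400),
    )


@pytest.fixture(scope="session")
def fitted(survey, survey_priors):
    """A short but well-mixed fit of the fixture survey."""
    model = CaptureRecaptureModel(survey.observations, survey_priors)
    return model.fit(n_chains=2, n_iter=6000, n_burn=2000, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
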