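import numpy as np
import pytest

import mwedist as mw

# parameter triples spanning the simulation study's truth values
STUDY_PARAMS = [
    (1.0, 1.0, 1.0),
    (1.0, 2.0, 1.0),
    (1.0, 2.0, 2.0),
    (2.0, 1.0, 1.0),
    (2.0, 2.0, 2.0),
    (0.1, 0.5, 0.1),
    (0.5, 0.5, 0.5),
    (0.1, 0.1, 0.1),
]


@pytest.fixture(scope="session")
def unit_params():
    return mw.Params(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def unit_prior():
    """Gamma priors with mean 1 and rate 1 on every coordinate."""
    return mw.elicit_prior([1.0, 1.0, 1.0])


@pytest.fixture(scope="session")
def census_sample_100(unit_params):
    """Seeded type-II censored sample, n=100, 20% censoring."""
    return mw.generate_censored_sample(100, 80, unit_params, seed=20210)


@pytest.fixture(scope="session")
def fitted_1000(unit_params, unit_prior):
    """A well-identified seeded sample (n=1000) with MLE and derivative bundle."""
    s = mw.generate_censored_sample(1000, 800, unit_params, seed=6)
    fit = mw.fit_mle(s)
    bundle = mw.derivative_bundle(
        s, fit.params, prior_gradient=mw.log_prior_gradient(fit.params, unit_prior)
    )
    return s, fit, bundle
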