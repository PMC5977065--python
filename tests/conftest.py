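import numpy as np
import pytest

import extractopt as xo


@pytest.fixture(scope="session")
def study_data():
    """The embedded 30-run glycyrrhizic-acid extraction CCD."""
    return xo.glycyrrhizic_ccd()


@pytest.fixture(scope="session")
def study_factors():
    return xo.glycyrrhizic_factors()


@pytest.fixture(scope="session")
def full_fit(study_data):
    """Full 15-term OLS fit plus its ANOVA, shared across tests."""
    model = xo.fit_quadratic(study_data)
    table = xo.anova(model, study_data)
    return model, table


@pytest.fixture(scope="session")
def pruned_model(study_data, full_fit):
    model, table = full_fit
    return xo.prune_nonsignificant(model, table)


@pytest.fixture(scope="session")
def reduced_surface():
    """The published reduced surface entered from its printed coefficients."""
    return xo.QuadraticModel.from_named_coefficients(xo.STUDY_SURFACE)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
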