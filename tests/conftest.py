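import numpy as np
import pytest

import extractopt as eo


@pytest.fixture(scope="session")
def fixture_table():
    return eo.paper_fixture()


@pytest.fixture(scope="session")
def fixture_model(fixture_table):
    return eo.fit_quadratic(fixture_table, coding="coded")


@pytest.fixture(scope="session")
def fixture_anova(fixture_model, fixture_table):
    return eo.anova(fixture_model, fixture_table)


@pytest.fixture(scope="session")
def design_box(fixture_table):
    return [(d.low, d.high) for d in fixture_table.domains]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_true_model(coding="coded", seed=1):
    """A random but reproducible ground-truth quadratic surface."""
    gen = np.random.default_rng(seed)
    coefs = gen.normal(0.0, 1.0, 14)
    return eo.QuadraticModel(intercept=15.0, coefficients=coefs,
                             coding=coding, domains=eo.PAPER_DOMAINS)
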