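import numpy as np
import pandas as pd
import pytest

from pbomics.synthetic import (
    default_ground_truth,
    make_design,
    metabolite_concentrations,
    simulate_expression,
)


@pytest.fixture(scope="session")
def design80():
    return make_design(5, seed=7)


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth(seed=7)


@pytest.fixture(scope="session")
def concentrations(design80, truth):
    return metabolite_concentrations(design80, truth)


@pytest.fixture(scope="session")
def expression(design80, truth, concentrations):
    values, flags = simulate_expression(
        design80, truth, n_null_genes=200, metabolite_table=concentrations
    )
    return values, flags


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_xy(rng):
    """Small regression problem with real X-Y structure."""
    X = rng.normal(size=(21, 6))
    beta = rng.normal(size=6)
    y = X @ beta + 0.3 * rng.normal(size=21)
    return X, y
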