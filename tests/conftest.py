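"""Shared fixtures: small synthetic surveys and fitted models.

Heavy objects (fitted models) are session-scoped so several test modules
can reuse them; problem sizes are kept small enough that the whole suite
runs on one CPU in minutes.
"""

import numpy as np
import pytest

from ppsdm import (
    default_params,
    make_domain,
    simulate_fields,
    simulate_survey,
)
from ppsdm.estimation import ModelSpec, fit


@pytest.fixture(scope="session")
def small_domain():
    """20 x 60 cells of 2.8 x 3.7 km: a compact shelf strip."""
    return make_domain(20, 60, (2.8, 3.7))


@pytest.fixture(scope="session")
def model1_data(small_domain):
    """Survey simulated under model-1 structure (spatial field + depth)."""
    params = default_params(n_years=8, stations_per_year=125, st_mode="none", seed=3)
    fields = simulate_fields(small_domain, params, seed=3)
    obs = simulate_survey(small_domain, fields, params, seed=3)
    return params, fields, obs


@pytest.fixture(scope="session")
def model1_fit(model1_data):
    """Model-1 fit (40 knots) with standard errors."""
    _, _, obs = model1_data
    spec = ModelSpec(include_depth=True, st_mode="none", n_knots=40,
                     n_starts=1, compute_se=True)
    res = fit(spec, obs)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
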