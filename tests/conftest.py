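import numpy as np
import pytest

from pecrisk.cohort import MaternalProfile
from pecrisk.params import MarkerModel, RiskModelParams, default_params
from pecrisk.synthetic import default_generator_config, simulate_cohort


@pytest.fixture(scope="session")
def params():
    """Shipped default parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def make_params():
    """Factory for compact parameter sets with controllable pieces."""

    def _make(mu0=52.0, sd=3.0, effects=None,
              slopes=(-0.004, -0.025, 0.03), changepoints=(40.0, 40.0, 40.0),
              resid_sd=(0.03, 0.12, 0.18), grid=(24.0, 42.0, 0.025)):
        markers = {}
        for name, s, cp in zip(("map", "uta_pi", "plgf"), slopes, changepoints):
            markers[name] = MarkerModel(name=name, intercept_log10=0.0,
                                        regression={}, slope=s, changepoint=cp)
        return RiskModelParams(
            prior_intercept=mu0, prior_sd=sd,
            prior_effects=effects or {},
            markers=markers,
            residual_cov=np.diag(np.square(resid_sd)),
            grid_min=grid[0], grid_max=grid[1], grid_step=grid[2],
        )

    return _make


@pytest.fixture(scope="session")
def reference_profile():
    return MaternalProfile.reference()


@pytest.fixture(scope="session")
def small_cohort():
    """500-row synthetic cohort for pipeline-level unit tests."""
    gc = default_generator_config(n=500, seed=42)
    return simulate_cohort(gc), gc
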