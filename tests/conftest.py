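import numpy as np
import pytest
from hypothesis import settings

from psmcea import PartitionedSurvivalCEA, default_config
from psmcea.synthetic import _quantile

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def calibrated_results(config):
    """Base case with person-times calibrated from the published costs."""
    return PartitionedSurvivalCEA(config).fit(calibrate_from_costs=True)


@pytest.fixture(scope="session")
def parametric_results(config):
    return PartitionedSurvivalCEA(config).fit()


def simulate_censored(dist, n, seed, cens_frac=0.3):
    """Draw right-censored survival data from a parametric distribution.

    Events are inverse-CDF draws; administrative censoring at the empirical
    (1 - cens_frac) quantile censors roughly that fraction of records.
    """
    rng = np.random.default_rng(seed)
    t = _quantile(dist, rng.uniform(size=n))
    if cens_frac > 0:
        c = np.quantile(t, 1.0 - cens_frac)
        event = t <= c
        t = np.where(event, t, c)
    else:
        event = np.ones(n, dtype=bool)
    return np.maximum(t, 1e-6), event
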