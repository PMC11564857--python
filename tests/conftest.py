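import numpy as np
import pytest

import tractstats as ts


@pytest.fixture(scope="session")
def default_cohort():
    """One concussion-like cohort at the default configuration (fixed seed)."""
    cfg = ts.SimulationConfig(seed=42)
    return ts.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_null_cohort():
    """A fast no-effect cohort with a single metric, independent tracts."""
    cfg = ts.SimulationConfig.null(
        n_group1=12, n_group2=12, inter_tract_rho=0.0,
        metrics=("DKI_FA",), seed=7)
    return ts.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
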