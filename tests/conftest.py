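import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methylboost.core_io import BetaMatrix
from methylboost.synthetic_data import SimulationConfig, gen_cohort_betas

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_beta() -> BetaMatrix:
    rng = np.random.default_rng(7)
    values = rng.uniform(0.05, 0.95, size=(10, 6))
    return BetaMatrix(pd.DataFrame(
        values,
        index=[f"cg{i:08d}" for i in range(10)],
        columns=[f"S{i}_T1" for i in range(6)]))


@pytest.fixture(scope="session")
def cohort():
    """Default study-shaped synthetic cohort (2,000 probes, 31 subjects)."""
    cfg = SimulationConfig(seed=123)
    beta, sheet, truth = gen_cohort_betas(cfg)
    return cfg, beta, sheet, truth
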