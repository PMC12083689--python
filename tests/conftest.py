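import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sirisurv as s

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signal_cohort() -> pd.DataFrame:
    """Planted-signal cohort used by several forest-level tests: wide SIRI
    scale (cutoff 3.5 admissible), strong threshold effects."""
    cfg = s.synthetic.CohortConfig(
        n_subjects=600, siri_log_sd=s.synthetic.SIRI_LOG_SD_WIDE, seed=42)
    return s.synthetic.generate_cohort(cfg, s.synthetic.strong_hazard_spec())


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    cfg = s.synthetic.CohortConfig(n_subjects=400, seed=43)
    return s.synthetic.generate_cohort(cfg, s.synthetic.null_hazard_spec())


@pytest.fixture(scope="session")
def signal_forest(signal_cohort) -> s.forest.SurvivalForest:
    return s.forest.fit_forest(
        signal_cohort, s.forest.ForestConfig(n_trees=300, seed=7))


def censored_instance(rng: np.random.Generator, n: int):
    """A random right-censored survival instance with ties possible."""
    times = np.round(rng.exponential(20, n), 0) + 1
    censor = np.round(rng.exponential(30, n), 0) + 1
    obs = np.minimum(times, censor)
    events = (times <= censor).astype(int)
    scores = rng.normal(size=n).round(1)  # rounding induces score ties
    return scores, obs, events
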