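import numpy as np
import pandas as pd
import pytest

from cotwin import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-structure cohort shared by read/write/score tests."""
    cfg = SimConfig(n_pairs_mz=40, n_pairs_dz=60, n_waves=4)
    cohort, truth = simulate_cohort(cfg, seed=11)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def flat_cohort():
    """Random-intercept-only cohort with a known direct SES effect."""
    cfg = SimConfig(
        n_pairs_mz=150,
        n_pairs_dz=250,
        delta=2.0,
        n_waves=4,
        dropout=0.1,
        pair_sd=(3.5, 0.0, 0.0),
        individual_sd=(3.5, 0.0, 0.0),
    )
    cohort, truth = simulate_cohort(cfg, seed=23)
    return cohort, truth, cfg


def standardized_ses(cohort, cfg, name="ses_z"):
    cohort.persons[name] = (cohort.persons[cfg.ses_name] - cfg.ses_mean) / cfg.ses_sd
    return cohort
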