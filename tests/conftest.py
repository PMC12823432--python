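"""Shared fixtures: small synthetic cohorts regenerated at test time."""

import numpy as np
import pytest

from organclock import (
    OutcomeSpec,
    SearchSpace,
    SimulationConfig,
    simulate_cohort,
)
from organclock.preprocess import preprocess_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Ten-organ cohort, small enough for unit tests."""
    return SimulationConfig(
        n_subjects=300,
        n_proteins_per_organ=6,
        frac_age_informative=0.34,
        noise_sd=0.25,
        missing_rate=0.03,
        outcome_specs=(
            OutcomeSpec("mortality", log_hr=0.3, baseline_hazard=0.03),
            OutcomeSpec("mci_transition", log_hr=0.4, kind="binary"),
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(cohort, discovery expr, confirmation expr, truth) for the small config."""
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_clean(small_sim):
    """Preprocessed (filtered + scaled) version of the small cohort."""
    cohort, *_ = small_sim
    clean, _, _ = preprocess_cohort(cohort)
    return clean


@pytest.fixture(scope="session")
def tiny_space() -> SearchSpace:
    """Cheap search space for unit tests of the training recipe."""
    return SearchSpace(
        n_trials=3, k_folds=3, max_estimators=80,
        min_child_samples=(5, 20), early_stopping_rounds=10,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
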