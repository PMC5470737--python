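"""Shared fixtures: solved strategies, simulated populations, synthetic cohorts.

Expensive objects (dynamic-programming solutions, 50,000-individual
simulations, register-scale cohorts) are session-scoped and shared across
test modules.
"""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from divdep import (
    CohortConfig,
    LifeHistoryParams,
    bin_prevalence,
    detrend_and_baseline,
    generate_cohort,
    simulate_population,
    solve_strategy,
)

REPO_ROOT = Path(__file__).resolve().parents[1]

# study-condition fixture: register-scale cohort, stress-relief episode truth
FIXTURE_SEED = 20170614
FIXTURE_CONFIG = dict(seed=FIXTURE_SEED)  # all other fields at their defaults


def make_fixture_series():
    """Regenerate the packaged synthetic prevalence fixture from its config."""
    cfg = CohortConfig(**FIXTURE_CONFIG)
    table = generate_cohort(cfg)
    divorced = bin_prevalence(table, centring="divorce")
    control = bin_prevalence(table, centring="calendar")
    return detrend_and_baseline(divorced, control), cfg


@pytest.fixture(scope="session")
def default_params():
    return LifeHistoryParams()


@pytest.fixture(scope="session")
def solved(default_params):
    return solve_strategy(default_params)


@pytest.fixture(scope="session")
def sim50k(solved, default_params):
    strategy, _ = solved
    return simulate_population(strategy, default_params, 50_000, seed=11)


@pytest.fixture(scope="session")
def fixture_series():
    series, _cfg = make_fixture_series()
    return series


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for structural tests (not for recovery accuracy)."""
    cfg = CohortConfig(n_individuals=20_000, divorced_fraction=0.3, seed=5)
    return cfg, generate_cohort(cfg)
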