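"""Shared fixtures: small synthetic cohorts and one reusable MCMC fit."""

import math

import numpy as np
import pytest

import relapsetrack as rt
from relapsetrack.censoring import FollowUpSchedule, censor_cohort
from relapsetrack.cohort import CohortConfig, RelapseProcess, generate_cohort, simulate_relapse_times

RECOVERY_SHAPE = 1.5
RECOVERY_EFFECT_DAYS = 2.6  # days per SOCRATES point
RECOVERY_MEAN_SURVIVAL = 220.0  # days at the configured SOCRATES mean


def recovery_process(shape=RECOVERY_SHAPE, effect=RECOVERY_EFFECT_DAYS, mean_survival=RECOVERY_MEAN_SURVIVAL):
    """Weibull AFT generating process with stated mean survival and effect."""
    g = math.gamma(1.0 + 1.0 / shape)
    slope = effect / g
    intercept = mean_survival / g - slope * 72.47
    return RelapseProcess(mode="weibull_aft", shape=shape, intercepts=intercept, motivation_coeff=slope)


def make_recovery_dataset(n=200, seed=0, process=None):
    """Cohort + censored outcomes from the recovery process."""
    process = process or recovery_process()
    cfg = CohortConfig(n_subjects=n, relapse_model=process, seed=seed)
    cohort = generate_cohort(cfg)
    times = simulate_relapse_times(cohort, process, seed=seed + 1)
    outcomes = censor_cohort(cohort, times, FollowUpSchedule(), 395)
    return cohort, times, outcomes


@pytest.fixture(scope="session")
def aft_fit():
    """One small grouped fit on a recovery cohort, shared across tests."""
    cohort, times, outcomes = make_recovery_dataset(n=150, seed=42)
    socrates = [s.socrates_total for s in cohort]
    groups = [s.group for s in cohort]
    mcmc = rt.McmcConfig(n_iterations=1200, burn_in=400, n_chains=2, seed=7)
    draws = rt.fit_interval_weibull(outcomes, socrates, groups, rt.SurvivalModelSpec(), mcmc)
    return {"cohort": cohort, "times": times, "outcomes": outcomes, "draws": draws}
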