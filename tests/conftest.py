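"""Shared fixtures: small synthetic cohorts and the replicated end-to-end runs.

The 20-replicate strong-effect and zero-effect pipeline runs are
expensive, so they are computed once per session and shared by every
test that asserts a property of them.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pytest

from noderad import CohortConfig, generate_cohort
from noderad.pipeline import RunConfig, run_pipeline

logging.disable(logging.WARNING)

N_STRONG_REPLICATES = 20
N_ZERO_REPLICATES = 10
REPLICATE_N = 400
REPLICATE_IMAGE = 36  # px; smaller than the 64 px default to keep the replicates fast
PREVALENCE = 87 / 391


def _run(cfg_factory, seed):
    cohort = cfg_factory(
        n_patients=REPLICATE_N, prevalence=PREVALENCE, image_size=REPLICATE_IMAGE, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(RunConfig(cohort=cohort, seed=seed))


@pytest.fixture(scope="session")
def strong_effect_runs():
    """20 full pipeline replicates on cohorts with a large injected class signal."""
    return [_run(CohortConfig.strong_effect, seed) for seed in range(N_STRONG_REPLICATES)]


@pytest.fixture(scope="session")
def zero_effect_runs():
    """Full pipeline replicates on cohorts with no image signal at all."""
    return [_run(CohortConfig.zero_effect, seed) for seed in range(N_ZERO_REPLICATES)]


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient strong-effect cohort for unit-level checks."""
    cfg = CohortConfig.strong_effect(n_patients=40, prevalence=0.25, image_size=40, seed=7)
    samples, split = generate_cohort(cfg)
    return cfg, samples, split


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
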