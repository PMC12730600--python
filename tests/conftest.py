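"""Shared fixtures: small synthetic cohorts generated once per session."""

import pytest

from mgportrait.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, 60 patients, used by read-only tests."""
    cfg = CohortConfig(n_patients=60, seed=42)
    table, covariates, truth = generate_cohort(cfg)
    return cfg, table, covariates, truth


@pytest.fixture(scope="session")
def midsize_cohort():
    """500-patient default cohort for structure-recovery tests."""
    cfg = CohortConfig(n_patients=500, seed=3)
    table, covariates, truth = generate_cohort(cfg)
    return cfg, table, covariates, truth
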