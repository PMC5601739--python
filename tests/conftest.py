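"""Shared fixtures: seeded synthetic cohorts and pipeline runs."""

import numpy as np
import pytest

from pepdiscover.pipeline import PipelineConfig, discover_from_spectra
from pepdiscover.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at 50/50, reused by cross-module tests."""
    return generate_cohort(CohortConfig(n_cases=50, n_controls=50, seed=7))


@pytest.fixture(scope="session")
def small_discovery(small_cohort):
    """One discovery-pipeline run on the 50/50 cohort (expensive; share it)."""
    return discover_from_spectra(
        small_cohort.spectra, small_cohort.labels, PipelineConfig()
    )


@pytest.fixture(scope="session")
def full_study():
    """Study-sized discovery (100/100) and validation (91/91) cohorts with a
    complete pipeline run; shared by end-to-end tests."""
    from pepdiscover.panel import external_validate
    from pepdiscover.pipeline import build_cohort_matrix, preprocess_cohort

    config = PipelineConfig()
    discovery = generate_cohort(
        CohortConfig(n_cases=100, n_controls=100, seed=11, cohort_id="discovery")
    )
    result = discover_from_spectra(discovery.spectra, discovery.labels, config)
    validation = generate_cohort(
        CohortConfig(n_cases=91, n_controls=91, seed=12, cohort_id="validation")
    )
    peaklists = preprocess_cohort(validation.spectra, config.preprocess)
    matrix_val = build_cohort_matrix(peaklists, validation.labels,
                                     config.align_tol_rel, "validation")
    perf_val = external_validate(result.model, matrix_val, config.align_tol_rel)
    return {
        "discovery_cohort": discovery,
        "result": result,
        "validation_cohort": validation,
        "matrix_val": matrix_val,
        "perf_val": perf_val,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
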