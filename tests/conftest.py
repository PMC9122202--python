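"""Shared fixtures: a small synthetic consortium and its full analysis.

Session-scoped so the multi-second end-to-end run is paid once; tests
must not mutate these objects.
"""

import dataclasses

import pytest

from stratmr import (
    PipelineSettings,
    SimulationConfig,
    analyze_consortium,
    generate_consortium,
)

SMALL_CONFIG = SimulationConfig(
    n_cohorts=3,
    cohort_sizes=(2500, 2000, 1200),
    hr_means=(67.0, 64.0, 71.0),
    age_means=(54.0, 62.0, 58.0),
    n_variants=20,
    binary_only_cohort_index=2,
    seed=20260925,
)


@pytest.fixture(scope="session")
def small_consortium():
    """Three cohorts (one binary-only) under default causal slopes."""
    return generate_consortium(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_result(small_consortium):
    cohorts, truth = small_consortium
    return analyze_consortium(cohorts, truth.weights, settings=PipelineSettings())


@pytest.fixture()
def tiny_config():
    """A fast-to-generate configuration for tests that rerun the generator."""
    return dataclasses.replace(
        SMALL_CONFIG,
        n_cohorts=2,
        cohort_sizes=(600, 400),
        hr_means=(67.0, 69.0),
        age_means=(55.0, 60.0),
        binary_only_cohort_index=None,
    )
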