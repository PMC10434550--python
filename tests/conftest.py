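"""Shared fixtures: default parameters and the session-scoped scenario runs
reused across metric, invariant and acceptance tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxsa import PhysiologyParams, compute_metrics, load_scenario, run_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", message="segment .* cuts a breath")


@pytest.fixture(scope="session")
def params() -> PhysiologyParams:
    return PhysiologyParams()


def _run(name, params, **kwargs):
    return run_scenario(load_scenario(name), params, **kwargs)


@pytest.fixture(scope="session")
def normal_result(params):
    """Normal-subject run (sinusoidal breathing, no events)."""
    return _run("normal_rest", params)


@pytest.fixture(scope="session")
def steady_cycle_mask(normal_result):
    """Several whole breathing cycles after stabilization."""
    t = normal_result.times
    return (t >= 390.0) & (t <= 480.0)


@pytest.fixture(scope="session")
def severe_result(params):
    """Severe-OSA run: four 40-s apneas with hyperventilation recovery."""
    return _run("severe_osa", params)


@pytest.fixture(scope="session")
def sim_results(params):
    """The mild/moderate/severe simulated OSA scenario battery."""
    names = (
        "mild_normal_recovery",
        "mild_hyperventilation_recovery",
        "moderate_short_apneas",
        "moderate_long_apneas",
        "severe_frequent_apneas",
        "moderate_medium_apneas",
    )
    return {name: _run(name, params) for name in names}


@pytest.fixture(scope="session")
def sim_metrics(sim_results):
    return {name: compute_metrics(res) for name, res in sim_results.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230803)
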