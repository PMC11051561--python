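"""Shared fixtures: small simulated studies reused across test modules."""

import pytest

from ednt.preprocess import preprocess
from ednt.simulate import CohortParams, simulate_study


@pytest.fixture(scope="session")
def child_study():
    """A 40-child simulated study with default population parameters."""
    return simulate_study(CohortParams(n_subjects=40), seed=11)


@pytest.fixture(scope="session")
def child_classified(child_study):
    classified, screening = preprocess(
        child_study.trials, child_study.schedule, "child"
    )
    return classified, screening


@pytest.fixture(scope="session")
def perfect_child_study():
    """Error-free, noiseless children: deterministic scoring oracle."""
    from ednt.simulate import BetaRate, PopulationEffect

    params = CohortParams(
        n_subjects=8,
        pes_population=PopulationEffect(0.0, 0.0),
        dd_population=PopulationEffect(200.0, 0.0),
        rt_noise_sd_ms=0.0,
        go_error_rate=BetaRate(0.0),
        nogo_false_alarm_rate=BetaRate(0.0),
        rt_family="normal",
    )
    return simulate_study(params, seed=21)
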