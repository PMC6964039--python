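"""Shared fixtures: expensive simulations are run once per session."""

import numpy as np
import pytest

from bovsim import (MetabolicParams, ReproductiveParams, Scenario, analyze,
                    simulate, simulate_metabolic)


@pytest.fixture(scope="session")
def mparams():
    return MetabolicParams()


@pytest.fixture(scope="session")
def rparams():
    return ReproductiveParams()


@pytest.fixture(scope="session")
def maintenance_run():
    """150-day coupled maintenance simulation with events attached."""
    res = simulate(Scenario.maintenance(horizon_d=150.0))
    analyze(res)
    return res


@pytest.fixture(scope="session")
def maintenance_metabolic_run():
    """100-day metabolic-only maintenance integration (dry cow)."""
    return simulate_metabolic(horizon_d=100.0)


@pytest.fixture(scope="session")
def chronic_run():
    """Chronic feed-restriction scenario (anchored to ovulation)."""
    res = simulate(Scenario.chronic_restriction(horizon_d=280.0))
    refeed = res.anchor_day + 30 * 7.0
    analyze(res, refeed_day=refeed)
    return res


@pytest.fixture(scope="session")
def lactation_runs():
    """Lactating scenarios for a small dietary glucose sweep."""
    out = {}
    for c0 in (0.2, 0.25, 0.3):
        res = simulate(Scenario.lactation(horizon_d=200.0, c0=c0))
        analyze(res)
        out[c0] = res
    return out
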