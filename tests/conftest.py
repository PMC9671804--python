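import numpy as np
import pytest

from stepcourse import studies, synthdata


@pytest.fixture(scope="session")
def small_sim():
    """One shared small simulated cohort (300 persons, 2 years)."""
    cfg = synthdata.SimConfig(n_participants=300, monitoring_years=2.0, seed=42)
    return synthdata.simulate(cfg)


def simulate_counting_table(seed: int, **kw):
    """One outcome's fit-ready counting-process table and companions.

    Returns (table, cohort, person_steps, hazard_spec, config).
    """
    out = studies.simulate_outcome_table(seed, **kw)
    return out["table"], out["cohort"], out["person_steps"], out["hazard_spec"], out["config"]


@pytest.fixture(scope="session")
def ct_factory():
    return simulate_counting_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
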