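import numpy as np
import pytest

from elonsim import (
    CodonTRNAMap,
    default_scenario,
    fixture_sequence,
    rescale_volume,
    run_simulation,
)


@pytest.fixture(scope="session")
def scenario():
    """Bundled in vivo scenario (0.064 um^3, mu = 1.1/h)."""
    return default_scenario()


@pytest.fixture(scope="session")
def scenario_small(scenario):
    """Concentration-preserving 0.008 um^3 scenario for cheap runs."""
    return rescale_volume(scenario, 0.008)


@pytest.fixture(scope="session")
def cmap():
    return CodonTRNAMap.load_default()


@pytest.fixture(scope="session")
def tufa(scenario):
    return fixture_sequence("tufa_like", trna=scenario.trna)


@pytest.fixture(scope="session")
def gfp(scenario):
    return fixture_sequence("gfp_like", trna=scenario.trna)


@pytest.fixture(scope="session", autouse=True)
def _warm_jit(scenario_small, tufa):
    # compile the event loop once so individual test timings are honest
    run_simulation(scenario_small, tufa, seed=0, stop_steps=20)
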