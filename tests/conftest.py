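import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metalsource.io_core import METALS, ConcentrationTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def random_table(rng: np.random.Generator, n: int = 30, species: bool = False) -> ConcentrationTable:
    """A positive random concentration table for oracle comparisons."""
    data = pd.DataFrame({"sample_id": [f"S{i:03d}" for i in range(n)]})
    if species:
        data["species"] = rng.choice(["sp_a", "sp_b", "sp_c"], size=n)
    data["x"] = rng.uniform(0, 30, n)
    data["y"] = rng.uniform(0, 30, n)
    for m in METALS:
        data[m] = rng.lognormal(mean=1.0, sigma=0.6, size=n)
    return ConcentrationTable(data)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def soil_table(rng):
    return random_table(rng, n=30)


@pytest.fixture
def preset_survey():
    from metalsource.synthetic import make_scenario, simulate_survey
    return simulate_survey(make_scenario(seed=7))
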