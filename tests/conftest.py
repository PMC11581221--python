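import pytest
from hypothesis import settings

from oryzasim import accumulate_gdd, synth_cultivar, synth_weather

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cultivar():
    return synth_cultivar(42)


@pytest.fixture(scope="session")
def gdd_series(cultivar):
    """A season long enough for every main-stem leaf to emerge."""
    temps = synth_weather(220, seed=42)
    return accumulate_gdd(temps, cultivar.base_temp)
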