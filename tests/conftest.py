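import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

from savhyd.climate import ClimateConfig, ClimateSeries, generate_climate
from savhyd.strategies import StrategySet, assemble_strategy_types
from savhyd.terrain import LOAMY_SAND


@pytest.fixture(scope="session")
def soil():
    return LOAMY_SAND


@pytest.fixture(scope="session")
def climate_config():
    return ClimateConfig()


@pytest.fixture(scope="session")
def short_climate(climate_config) -> ClimateSeries:
    """Three years of default synthetic weather, fixed seed."""
    return generate_climate(climate_config, 3, 20_001)


@pytest.fixture(scope="session")
def grazing_strategies() -> StrategySet:
    return assemble_strategy_types(land_use="grazing")


@pytest.fixture(scope="session")
def browsing_strategies() -> StrategySet:
    return assemble_strategy_types(land_use="browsing")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
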