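import pytest

from agdyn import GameConfig, PopulationSpec


@pytest.fixture
def dg_config() -> GameConfig:
    return GameConfig(variant="dg")


@pytest.fixture
def ag_restricted() -> GameConfig:
    """AG with receiver expectations capped at half the endowment."""
    return GameConfig(variant="ag", q_max=5)


@pytest.fixture
def noisy_ag_restricted() -> GameConfig:
    return GameConfig(variant="noisy_ag", q_max=5)


@pytest.fixture
def dg_spec(dg_config) -> PopulationSpec:
    return PopulationSpec.from_config(dg_config, N=100)


@pytest.fixture
def ag_spec(ag_restricted) -> PopulationSpec:
    return PopulationSpec.from_config(ag_restricted, N=100)


@pytest.fixture
def small_ag_spec(ag_restricted) -> PopulationSpec:
    """Smaller population for iteration-heavy checks."""
    return PopulationSpec.from_config(ag_restricted, N=50)
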