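import pytest

from samplecast import Scenario, TimeModel


@pytest.fixture
def three_pct_scenario():
    """3% imaginary-disease scenario on the 58.7 M population, 1 h/day."""
    return Scenario(population_size=58_746_995, prevalence_pct=3)


@pytest.fixture
def migraine_scenario():
    """Migraine (12%) on the 12.3 M Jammu & Kashmir population, 1 h/day."""
    return Scenario(population_size=12_300_000, prevalence_pct=12)


@pytest.fixture
def kidney_scenario():
    """Nephrolithiasis (15%) on the same 12.3 M population."""
    return Scenario(population_size=12_300_000, prevalence_pct=15)


@pytest.fixture
def default_time_model():
    return TimeModel()
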