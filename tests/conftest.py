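import numpy as np
import pytest

from hmispipe import synthetic


def seasonal(amplitude: float = 0.05) -> list[float]:
    """12 multiplicative factors whose product is exactly 1."""
    x = amplitude * np.sin(2 * np.pi * np.arange(12) / 12)
    return list(np.exp(x - x.mean()))


@pytest.fixture
def small_scenario():
    """3 districts x 2 services x 24 months, clean reporting."""
    return synthetic.ScenarioConfig(
        n_districts=3, start=201901, end=202012,
        services=("ANC1", "OPD"),
        baseline_level={"ANC1": 400.0, "OPD": 5000.0},
        annual_growth={"ANC1": 0.02, "OPD": 0.01},
        seasonal_factors={"ANC1": seasonal(0.05)},
        level_cv=0.2, seed=42)


@pytest.fixture
def messy_scenario():
    """Incomplete reporting plus injected missing values and outliers."""
    return synthetic.ScenarioConfig(
        n_districts=8, start=201801, end=202012,
        services=("ANC1", "DELIV"),
        completeness_mean=0.85, completeness_concentration=30,
        q_nonreporting=0.25, missing_rate=0.01, outlier_rate=0.005,
        level_cv=0.3, seed=7)


@pytest.fixture
def messy_records(messy_scenario):
    return synthetic.simulate(messy_scenario)
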