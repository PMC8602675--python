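import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from airburden import SyntheticConfig, generate_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel() -> pd.DataFrame:
    """The default synthetic world at seed 1."""
    return generate_panel(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_panel() -> pd.DataFrame:
    """Deterministic panel: outcome is an exact function of the exposures."""
    return generate_panel(SyntheticConfig(seed=1, noise_sd=0.0))


def end_year_slice(panel: pd.DataFrame, year: int = 2019) -> pd.DataFrame:
    """All-cause, all-pollutant slice of one year."""
    return panel[
        (panel["cause"] == "all_cause")
        & (panel["pollutant"] == "all")
        & (panel["year"] == year)
    ]
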