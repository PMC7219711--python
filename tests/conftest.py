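import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import obesity_elasticity as oe

settings.register_profile(
    "det", derandomize=True, max_examples=25, suppress_health_check=list(HealthCheck)
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tiny_config() -> oe.GeneratorConfig:
    """A small but structurally complete generator configuration."""
    return oe.GeneratorConfig(
        n_countries=30,
        n_years=16,
        strata=("overall",),
        bridge_years=(1991, 1992),
        horizon_years=(1993, 1998),
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config) -> oe.SyntheticDataset:
    return oe.generate_dataset(tiny_config, seed=11)


@pytest.fixture(scope="session")
def default_overall_dataset() -> oe.SyntheticDataset:
    """One full-size (147 × 40) dataset, overall stratum only."""
    return oe.generate_dataset(oe.GeneratorConfig(strata=("overall",)), seed=5)


@pytest.fixture
def small_panel_frame() -> pd.DataFrame:
    """A clean 3-country hand-written panel frame."""
    rows = []
    rng = np.random.default_rng(0)
    for country in ("AAA", "BBB", "CCC"):
        for year in (2000, 2001, 2002, 2003):
            rows.append(
                (country, year, "overall", 10 + rng.uniform(0, 5), 5000 + rng.uniform(0, 500))
            )
    return pd.DataFrame(
        rows, columns=["country", "year", "stratum", "prevalence_pct", "gdppc"]
    )
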