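import numpy as np
import pandas as pd
import pytest

from dietopt.pipeline import CountryContext, make_context
from dietopt.synthetic import GeneratorConfig, generate_country_dataset


@pytest.fixture(scope="session")
def us_dataset():
    return generate_country_dataset(GeneratorConfig(seed=1, archetype="us_like"))


@pytest.fixture(scope="session")
def us_context(us_dataset) -> CountryContext:
    profile, records = us_dataset
    return make_context(profile, records)


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """Two-commodity table: high-emission beef vs cheap low-emission poultry.

    Both supply vitamin B12, so nutrition can be met either way; beef is far
    dirtier and slightly pricier per kg.
    """
    return pd.DataFrame({
        "category": ["beef", "poultry"],
        "producer_price": [3.0, 2.0],        # $/kg
        "emission_factor": [100.0, 4.0],     # kg CO2e/kg
        "protein": [26.0, 27.0],             # per 100 g
        "vitamin_a": [10.0, 15.0],
        "vitamin_b12": [2.5, 0.4],
        "ala": [0.05, 0.05],
        "epa": [0.01, 0.01],
        "dha": [0.005, 0.02],
        "energy": [250.0, 190.0],
    }, index=pd.Index(["beef", "poultry"], name="item_id"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
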