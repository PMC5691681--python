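import numpy as np
import pandas as pd
import pytest

from medgxe.dietary import RAW_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_profiles(rng, n, energy_mean=2400.0):
    """Random right-skewed diet profiles with positive energy."""
    medians = {
        "vegetables_g": 300.0,
        "legumes_g": 30.0,
        "fruits_g": 250.0,
        "nuts_g": 15.0,
        "cereals_g": 350.0,
        "fish_g": 20.0,
        "meat_poultry_g": 60.0,
        "dairy_g": 250.0,
        "mufa_g": 26.0,
        "sfa_g": 25.0,
    }
    df = pd.DataFrame({"subject_id": [f"P{i}" for i in range(n)]})
    for col in RAW_COLUMNS:
        if col == "energy_kcal":
            df[col] = energy_mean * np.exp(0.4 * rng.standard_normal(n))
        else:
            df[col] = medians[col] * np.exp(0.5 * rng.standard_normal(n))
    return df


@pytest.fixture
def profiles(rng):
    return make_profiles(rng, 200)


@pytest.fixture
def sex200(rng):
    return pd.Series(rng.choice(["male", "female"], size=200))
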