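import numpy as np
import pandas as pd
import pytest

from pupscales.core_data import Cohort
from pupscales.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-sized default-config synthetic cohort shared across tests."""
    cohort, truth = generate_cohort(GeneratorConfig(n_dogs=500, seed=7))
    return cohort, truth


@pytest.fixture()
def registry_df():
    return pd.DataFrame(
        {
            "dog_id": ["d1", "d2", "d3"],
            "breed": ["Lab", "GR", "GSD"],
            "sex": ["M", "F", "M"],
            "birth_date": pd.to_datetime(["2012-01-01", "2012-02-01", "2012-03-01"]),
            "training_entry_date": pd.to_datetime(
                ["2013-03-01", "2013-04-01", "2013-05-01"]
            ),
            "outcome": ["qualified", "withdrawn_behaviour", "qualified"],
            "outcome_date": pd.to_datetime(["2013-11-01", "2013-06-01", "2013-12-01"]),
        }
    )


@pytest.fixture()
def responses_df():
    return pd.DataFrame(
        {
            "dog_id": ["d1", "d1", "d2", "d2", "d3", "d3"],
            "age_point": ["5M", "8M", "5M", "8M", "5M", "8M"],
            "item_id": ["stubborn", "stubborn", "stubborn", "friendly", "friendly", "stubborn"],
            "value": [40.0, 55.0, np.nan, 80.0, 72.0, 31.0],
        }
    )


@pytest.fixture()
def tiny_cohort(registry_df, responses_df):
    return Cohort(dogs=registry_df, responses=responses_df)


@pytest.fixture()
def cohort_files(tmp_path, registry_df, responses_df):
    """The tiny cohort written out as CSV files (NK token included)."""
    reg = tmp_path / "registry.csv"
    resp = tmp_path / "responses.csv"
    out = registry_df.copy()
    for c in ("birth_date", "training_entry_date", "outcome_date"):
        out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(reg, index=False)
    r = responses_df.copy()
    r["value"] = [("NK" if pd.isna(v) else f"{v:g}") for v in r["value"]]
    r.to_csv(resp, index=False)
    return reg, resp
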