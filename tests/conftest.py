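import numpy as np
import pandas as pd
import pytest

import stuntgeo as sg


@pytest.fixture(scope="session")
def lms_table() -> pd.DataFrame:
    """Small synthetic LMS reference covering 0-59 months, both sexes.

    Median length grows smoothly with age; the L power varies so both the
    Box-Cox and the log branches of the z-score formula get exercised.
    """
    rows = []
    for sex in ("male", "female"):
        for age in range(60):
            m = 50.0 + 0.8 * age * (1 - age / 200) + (0.5 if sex == "male" else 0.0)
            l = 1.0 - 0.02 * (age % 30)
            rows.append({"sex": sex, "age_months": age, "L": round(l, 3),
                         "M": round(m, 2), "S": 0.04})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_region() -> sg.synthetic.StudyRegion:
    return sg.generate_study_region(n_kebeles=6, n_villages=10, extent_km=20, seed=7)


@pytest.fixture(scope="session")
def study_dataset():
    """One moderate synthetic survey shared across read-only tests."""
    region, truth, records = sg.generate_dataset(seed=11, n_children=1500)
    return region, truth, records


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
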