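import numpy as np
import pandas as pd
import pytest

from insmark.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient synthetic cohort with default study conditions."""
    cohort, truth = simulate_cohort(SimConfig(n=400), seed=11)
    return cohort, truth


@pytest.fixture(scope="session")
def medium_cohort():
    """1,500-patient synthetic cohort for discrimination checks."""
    cohort, truth = simulate_cohort(SimConfig(n=1500), seed=23)
    return cohort, truth


@pytest.fixture()
def complete_record():
    """One fully-observed patient row in canonical units."""
    return pd.Series({
        "sex": "male", "height": 170.0, "weight": 65.0, "bmi": 65.0 / 1.7 ** 2,
        "wbc": 6.5, "neutrophils": 4.2, "lymphocytes": 1.4, "platelets": 250.0,
        "rbc": 4.6, "hemoglobin": 140.0, "albumin": 42.0, "crp": 5.0,
        "glucose": 5.3, "total_protein": 70.0, "cholesterol": 4.5,
    })


def random_censored_dataset(rng, n, frac_censored=0.3):
    """Random survival data with ties in times and risks."""
    times = rng.integers(1, max(4, n // 3), n).astype(float)
    events = (rng.random(n) > frac_censored).astype(int)
    risk = np.round(rng.normal(size=n), 1)  # rounding forces ties
    return times, events, risk
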