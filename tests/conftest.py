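import numpy as np
import pandas as pd
import pytest

from fairdem.cohort import build_cohort
from fairdem.config import PopulationConfig
from fairdem.synthetic import generate_population


def quick_population(n=800, seed=0, **overrides):
    """A lighter visit process for unit tests (fewer visits per year)."""
    params = dict(
        n_patients=n,
        seed=seed,
        n_categories=8,
        visits_per_year_mean={"case": 5.0, "control": 4.0},
    )
    params.update(overrides)
    return PopulationConfig(**params)


@pytest.fixture(scope="session")
def big_tables():
    """Default-configuration population at n=10,000 (shared across tests
    that check marginal/concordance/prevalence recovery)."""
    cfg = PopulationConfig(n_patients=10_000, seed=7)
    patients, visits = generate_population(cfg)
    return cfg, patients, visits


@pytest.fixture(scope="session")
def big_cohort(big_tables):
    cfg, patients, visits = big_tables
    cohort, ledger = build_cohort(patients, visits, seed=11)
    return cohort, ledger, visits


@pytest.fixture(scope="session")
def small_run():
    """Small end-to-end-ready tables with the quick visit process."""
    cfg = quick_population(n=700, seed=3)
    patients, visits = generate_population(cfg)
    cohort, ledger = build_cohort(patients, visits, seed=5)
    return cfg, patients, visits, cohort, ledger


def make_predictions(
    n=400, ber_low=0.45, ber_high=0.25, low_frac=0.3, pos_frac=0.4, seed=0
):
    """Construct a prediction table with designed subgroup error rates
    (equal FPR and FNR within each SES level, so BER is exact by design)."""
    rng = np.random.default_rng(seed)
    ses = np.where(rng.random(n) < low_frac, "low", "high")
    y = (rng.random(n) < pos_frac).astype(int)
    err_p = np.where(ses == "low", ber_low, ber_high)
    wrong = rng.random(n) < err_p
    y_pred = np.where(wrong, 1 - y, y)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "y_true": y,
            "y_pred": y_pred,
            "sex": sex,
            "ses_m1": ses,
            "ses_m2": ses,
            "ses_m3": ses,
        }
    )
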