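import numpy as np
import pandas as pd
import pytest

from albuscreen import CohortSimParams, ModelParameters, generate_cohort

#: Confusion counts of the five strategies against the three-month gold
#: standard in the cohort study (n=157), used as frozen inputs in tests.
STUDY_COUNTS = {
    "DAY1": (82, 23, 52, 0),  # tp, fp, tn, fn
    "RANDOM": (79, 40, 35, 3),
    "DAY1_RANDOM": (79, 18, 57, 3),
    "DAY1_DAY2": (79, 17, 58, 3),
    "DAY1_RANDOM_DAY2": (77, 14, 61, 5),
}


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSimParams(seed=42))


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSimParams(n_patients=10_000, seed=7))


@pytest.fixture()
def base_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture()
def noise_free_params() -> CohortSimParams:
    """Zero within-person noise, set-points bracketing the threshold."""
    return CohortSimParams(
        n_patients=157,
        prevalence_persistent=82 / 157,
        log_acr_mean_persistent=np.log(100.0),
        log_acr_mean_transient=np.log(10.0),
        log_acr_sd_between_persistent=0.0,
        log_acr_sd_between_transient=0.0,
        cv_day_to_day=0.0,
        cv_intraday_extra=0.0,
        random_spot_shift=1.0,
        seed=3,
    )
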