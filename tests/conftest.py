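import numpy as np
import pandas as pd
import pytest

import ccsurv as cc
from ccsurv.simulate import BiomarkerSpec, EndpointSpec, SimulationConfig


def single_marker_config(n: int, seed: int, log_hr: float = 0.0,
                         incidence: float = 0.10, **kwargs) -> SimulationConfig:
    """Minimal one-biomarker cohort: the workhorse for recovery/coverage
    simulations where the full covariate panel is irrelevant."""
    return SimulationConfig(
        n_subjects=n,
        biomarkers=(BiomarkerSpec("bm", 0.0, 1.0),),
        biomarker_corr=np.eye(1),
        endpoints=(EndpointSpec("e", 1.3, 40.0, log_hr={"bm": log_hr},
                                target_incidence=incidence),),
        frailty_sd=0.0,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """3000-subject default cohort shared across read-only tests."""
    return cc.simulate_cohort(cc.default_config(n_subjects=3000, seed=7))


@pytest.fixture(scope="session")
def diabetes_sample(small_cohort) -> cc.CaseCohortSample:
    return cc.draw_subcohort(small_cohort, cc.SamplingDesign(fractions=0.2, seed=3),
                             "diabetes")


def toy_cohort(times, statuses, x, endpoint="e") -> pd.DataFrame:
    n = len(times)
    return pd.DataFrame({
        "id": np.arange(1, n + 1), "survey": "S1", "sex": "female",
        "x": np.asarray(x, dtype=float),
        f"time_{endpoint}": np.asarray(times, dtype=float),
        f"status_{endpoint}": np.asarray(statuses, dtype=int),
    })
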