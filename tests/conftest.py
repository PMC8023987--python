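import numpy as np
import pandas as pd
import pytest

from trajmix import simulate
from trajmix.cohort import Cohort, truncate_followup


@pytest.fixture
def tiny_cohort():
    """Two patients, hand-written records."""
    baseline = pd.DataFrame({
        "patient_id": ["a", "b"],
        "sex": ["F", "M"],
        "ethnicity": ["white", "black"],
        "diagnosis": ["definite_jdm", "jdm_overlap"],
        "centre": ["A", "Other"],
        "age_at_diagnosis": [6.0, 9.5],
        "time_to_first_visit": [0.2, 1.0],
        "pga0": [3.0, np.nan],
        "cmas0": [40.0, 30.0],
        "das0": [3.0, 2.0],
        "arthritis": [0.0, 1.0],
        "abnormal_respiration": [0.0, np.nan],
        "calcinosis": [np.nan, 0.0],
        "lipodystrophy": [0.0, 0.0],
        "ulceration": [1.0, 0.0],
    })
    visits = pd.DataFrame({
        "patient_id": ["a", "a", "a", "b", "b"],
        "t": [0.2, 1.0, 2.5, 1.0, 3.0],
        "pga": [3.0, 2.0, np.nan, 5.0, 4.0],
        "das": [3.0, 1.0, 1.0, 2.0, 2.0],
        "gottron": [1.0, 1.0, 1.0, 1.0, 1.0],
        "heliotrope": [1.0, 0.0, 0.0, 1.0, 0.0],
        "vasculitis": [0.0, 0.0, 0.0, 0.0, 1.0],
        "erythema": [1.0, 0.0, 0.0, 0.0, 0.0],
    })
    return Cohort(baseline=baseline, visits=visits)


@pytest.fixture(scope="session")
def sim_cohort_small():
    """Simulated 2-class cohort, truncated, reused across tests (read-only)."""
    spec = simulate.default_study_spec(n_patients=250, seed=42)
    cohort, truth = simulate.simulate_cohort(spec)
    return truncate_followup(cohort, 10.0), truth, spec
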