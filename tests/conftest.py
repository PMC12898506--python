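import numpy as np
import pytest

from akiews import SimConfig, simulate_cohort
from akiews.synthetic_cohort import StayRecord

STRONG_EFFECTS = {"map_downtrend": 1.8, "low_uo": 1.6, "sepsis_flag": 1.2,
                  "ckd_flag": 1.0, "age": 0.6}
NULL_EFFECTS = {k: 0.0 for k in STRONG_EFFECTS}


@pytest.fixture(scope="session")
def small_cohort():
    """50 mixed stays used by the labeler-equivalence and invariant tests."""
    return simulate_cohort(SimConfig(n_patients=50, seed=7))


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium cohort with strong planted effects for model-level tests."""
    cfg = SimConfig(n_patients=300, seed=21, baseline_insult_hazard=0.0015,
                    effect_sizes=STRONG_EFFECTS, prodrome_lead=24.0)
    return simulate_cohort(cfg)


def make_stay(stay_id="S1", patient_id="P1", age=60.0, discharge=96.0,
              labs=None, urine=None, weights=None, rrt=None, vitals=None,
              eskd=0, age_masked=False, comorbidities=None, treatments=None):
    """Hand-built minimal stay for unit tests."""
    empty = (np.array([]), np.array([]))
    return StayRecord(
        patient_id=patient_id, stay_id=stay_id, age=age, age_masked=age_masked,
        sex="F", race="White", unit_type="MICU",
        comorbidities=comorbidities or {}, eskd_status=eskd,
        discharge_time=discharge, vitals=vitals or {},
        labs={k: (np.asarray(t, float), np.asarray(v, float))
              for k, (t, v) in (labs or {}).items()},
        urine_output=(np.asarray(urine[0], float), np.asarray(urine[1], float))
        if urine else empty,
        weights=(np.asarray(weights[0], float), np.asarray(weights[1], float))
        if weights else empty,
        treatments=treatments or [], rrt_episodes=rrt or [])
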