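import numpy as np
import pandas as pd
import pytest

from obesity_lca.cohort_builder import CohortTables
from obesity_lca.scenarios import recovery_config, simple_demographics
from obesity_lca.synthetic_cohort import GeneratorConfig, generate_cases
from obesity_lca.temporal import TemporalDiagnosis


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-class, 8-feature case cohort of 600 patients (session-cached)."""
    config = recovery_config(seed=123, n_cases=600, k=2, n_items=8)
    return generate_cases(config)


@pytest.fixture
def two_class_config():
    vocab = [TemporalDiagnosis(1, c) for c in "ABCD"]
    return GeneratorConfig(
        n_cases=2000,
        k_true=2,
        mixing_weights=np.array([0.5, 0.5]),
        item_probs=np.array([[0.9, 0.8, 0.2, 0.1], [0.1, 0.2, 0.7, 0.6]]),
        vocabulary=vocab,
        demographic_params=simple_demographics(2),
        seed=99,
    )


def make_visits(pid, flags_days, roles=None, insurance=None):
    """Visit table rows for one patient from (obese_flag, day) tuples."""
    rows = []
    for j, (flag, day) in enumerate(flags_days):
        rows.append(
            {
                "visit_id": f"{pid}-v{j}",
                "patient_id": pid,
                "visit_role": roles[j] if roles else "other",
                "day_offset": day,
                "obese_flag": int(flag),
                "insurance": insurance[j] if insurance else "",
            }
        )
    return rows


def make_cohort(visit_rows, diagnoses=None, patients=None, match_pairs=None):
    pids = sorted({r["patient_id"] for r in visit_rows})
    if patients is None:
        patients = pd.DataFrame(
            {
                "patient_id": pids,
                "cohort": "case",
                "match_id": pids,
                "sex": "Male",
                "race": "White",
                "ethnicity": "Not Hispanic or Latino",
                "philadelphia_resident": 0,
                "birth_offset_days": -3000,
            }
        )
    dx = pd.DataFrame(diagnoses or [], columns=["visit_id", "code"])
    return CohortTables(patients, pd.DataFrame(visit_rows), dx, match_pairs or {})
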