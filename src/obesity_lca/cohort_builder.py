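"""Cohort construction: visit roles, inclusion rules, features, demographics.

Input surface is three relational tables (patients, visits, diagnoses) in the
schema written by :mod:`obesity_lca.synthetic_cohort` — or real EHR extracts in
the same schema. This module

* identifies each case patient's index visit (first visit with an obese BMI),
  the pre-index visit (latest visit before it, required for inclusion) and the
  post-index visit (earliest visit after it, optional);
* derives the binary patient × temporal-diagnosis feature matrix;
* classifies race/ethnicity, Medicaid/CHIP enrollment (with the one-year
  fallback window and drop rule), and age categories.

Exclusions are never exceptions: excluded patients are recorded with a reason
(``no_visits``, ``no_index``, ``no_pre_index``, ``no_insurance_within_year``)
in an exclusion log that travels with the tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .temporal import ROLE_TO_TIMING, TemporalDiagnosis, canonical_order

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = [
    "patient_id",
    "cohort",
    "match_id",
    "sex",
    "race",
    "ethnicity",
    "philadelphia_resident",
    "birth_offset_days",
]
VISIT_COLUMNS = ["visit_id", "patient_id", "visit_role", "day_offset", "obese_flag", "insurance"]
DIAGNOSIS_COLUMNS = ["visit_id", "code"]

EXCLUSION_NO_VISITS = "no_visits"
EXCLUSION_NO_INDEX = "no_index"
EXCLUSION_NO_PRE_INDEX = "no_pre_index"
EXCLUSION_NO_INSURANCE = "no_insurance_within_year"
EXCLUSION_PARTNER = "match_partner_excluded"

#: sentinel returned by :func:`classify_medicaid` when a patient has no
#: insurance information on any visit within the lookback window
DROPPED = "DROPPED"

DAYS_PER_YEAR = 365.25

MEDICAID_PAYERS = frozenset({"Medicaid", "CHIP"})

RACE_PASSTHROUGH = {
    "Asian": "Asian",
    "Black/African American": "Black/African American",
    "Black or African American": "Black/African American",
    "White": "White",
    "Multiple Race": "Multiple Race",
    "More than one race": "Multiple Race",
}

HISPANIC_ETHNICITIES = frozenset({"Hispanic", "Hispanic or Latino", "Latino"})

AGE_CATEGORIES = ["2-4", "5-11", "12-18"]


@dataclass
class CohortTables:
    """Patients/visits/diagnoses relational tables plus case-control pairing.

    ``match_pairs`` maps case patient id → control patient id and must be
    injective. ``exclusions`` accumulates (patient_id, reason) rows as
    inclusion rules are applied.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    diagnoses: pd.DataFrame
    match_pairs: dict[str, str] = field(default_factory=dict)
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["patient_id", "reason"])
    )

    def __post_init__(self) -> None:
        controls = list(self.match_pairs.values())
        if len(set(controls)) != len(controls):
            raise ValueError("match_pairs must be injective (one control per case)")

    def case_ids(self) -> list[str]:
        return self.patients.loc[self.patients["cohort"] == "case", "patient_id"].tolist()

    def control_ids(self) -> list[str]:
        return self.patients.loc[self.patients["cohort"] == "control", "patient_id"].tolist()

    def subset(self, patient_ids) -> "CohortTables":
        ids = set(patient_ids)
        patients = self.patients[self.patients["patient_id"].isin(ids)].reset_index(drop=True)
        visits = self.visits[self.visits["patient_id"].isin(ids)].reset_index(drop=True)
        vids = set(visits["visit_id"])
        diagnoses = self.diagnoses[self.diagnoses["visit_id"].isin(vids)].reset_index(drop=True)
        pairs = {c: t for c, t in self.match_pairs.items() if c in ids and t in ids}
        return CohortTables(patients, visits, diagnoses, pairs, self.exclusions.copy())


@dataclass
class FeatureMatrix:
    """Binary patient × temporal-diagnosis grid.

    ``data`` is indexed by patient id with one uint8 column per vocabulary
    item, columns in canonical (timing, code) order and rendered ``"t-code"``.
    """

    data: pd.DataFrame
    vocabulary: list[TemporalDiagnosis]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def item_sets(self) -> dict[str, frozenset[TemporalDiagnosis]]:
        """Per-patient sets of present temporal diagnoses (for containment tests)."""
        arr = self.data.to_numpy()
        vocab = self.vocabulary
        return {
            pid: frozenset(vocab[j] for j in np.nonzero(arr[i])[0])
            for i, pid in enumerate(self.data.index)
        }


def _ordered_visits(visits: pd.DataFrame) -> pd.DataFrame:
    # same-day ties broken by visit_id so role assignment is deterministic
    return visits.sort_values(["day_offset", "visit_id"], kind="mergesort")


def identify_index_visits(tables: CohortTables) -> CohortTables:
    """Assign visit roles for case patients and apply inclusion rules.

    Per case patient: the index visit is the first visit (in day order) with
    an obese BMI; the pre-index visit is the latest visit before it; the
    post-index visit is the earliest visit after it, if any. Patients whose
    first visit is already obese have no pre-index visit and are excluded, as
    are patients with no visits or no obese visit at all. Control patients
    keep the roles recorded in the visits table (their reference visit was
    assigned at matching time).
    """
    visits = tables.visits.copy()
    case_ids = set(tables.case_ids())
    excluded: list[tuple[str, str]] = []
    role = visits["visit_role"].copy()

    visits_by_patient = {
        pid: grp for pid, grp in _ordered_visits(visits).groupby("patient_id", sort=False)
    }
    for pid in tables.patients.loc[tables.patients["cohort"] == "case", "patient_id"]:
        grp = visits_by_patient.get(pid)
        if grp is None or len(grp) == 0:
            excluded.append((pid, EXCLUSION_NO_VISITS))
            continue
        obese_pos = np.nonzero(grp["obese_flag"].to_numpy())[0]
        if len(obese_pos) == 0:
            excluded.append((pid, EXCLUSION_NO_INDEX))
            continue
        idx = obese_pos[0]
        if idx == 0:
            excluded.append((pid, EXCLUSION_NO_PRE_INDEX))
            continue
        new_roles = np.array(["other"] * len(grp), dtype=object)
        new_roles[idx] = "index"
        new_roles[idx - 1] = "pre"
        if idx + 1 < len(grp):
            new_roles[idx + 1] = "post"
        role.loc[grp.index] = new_roles

    excluded_ids = {pid for pid, _ in excluded}
    visits["visit_role"] = role
    patients = tables.patients[~tables.patients["patient_id"].isin(excluded_ids)].reset_index(
        drop=True
    )
    # drop matched controls of excluded cases to keep pairing total
    orphan_controls = {tables.match_pairs[c] for c in excluded_ids if c in tables.match_pairs}
    excluded.extend((pid, EXCLUSION_PARTNER) for pid in sorted(orphan_controls))
    patients = patients[~patients["patient_id"].isin(orphan_controls)].reset_index(drop=True)
    keep = set(patients["patient_id"])
    visits = visits[visits["patient_id"].isin(keep)].reset_index(drop=True)
    diagnoses = tables.diagnoses[
        tables.diagnoses["visit_id"].isin(set(visits["visit_id"]))
    ].reset_index(drop=True)
    pairs = {c: t for c, t in tables.match_pairs.items() if c in keep}
    exclusions = pd.concat(
        [tables.exclusions, pd.DataFrame(excluded, columns=["patient_id", "reason"])],
        ignore_index=True,
    )
    if excluded:
        logger.info("excluded %d case patients: %s", len(excluded), dict(excluded[:5]))
    out = CohortTables(patients, visits, diagnoses, pairs, exclusions)
    _check_case_roles(out, case_ids - excluded_ids)
    return out


def _check_case_roles(tables: CohortTables, case_ids: set[str]) -> None:
    roles = tables.visits[tables.visits["patient_id"].isin(case_ids)]
    counts = roles.groupby("patient_id")["visit_role"].apply(
        lambda s: (list(s).count("pre"), list(s).count("index"))
    )
    bad = counts[counts != (1, 1)]
    if len(bad):
        raise AssertionError(f"role assignment failed for patients: {list(bad.index)[:5]}")


def build_temporal_features(
    tables: CohortTables, vocabulary: list[TemporalDiagnosis] | None = None
) -> FeatureMatrix:
    """Binarize the cohort: entry (patient, ``"t-code"``) = 1 iff the patient
    has that diagnosis code at the visit with role t.

    The vocabulary defaults to all observed temporal diagnoses (canonical
    order) but can be restricted, e.g. to the significant individual temporal
    diagnoses selected for latent class modelling. Diagnoses at visits with
    role ``other`` are ignored; a diagnosis row pointing at an unknown visit
    is an input-integrity error.
    """
    visits = tables.visits
    known = set(visits["visit_id"])
    unknown = ~tables.diagnoses["visit_id"].isin(known)
    if unknown.any():
        bad = tables.diagnoses.loc[unknown, "visit_id"].iloc[0]
        raise ValueError(f"diagnosis row references unknown visit {bad!r}")

    merged = tables.diagnoses.merge(
        visits[["visit_id", "patient_id", "visit_role"]], on="visit_id", how="left"
    )
    merged = merged[merged["visit_role"].isin(ROLE_TO_TIMING)]
    observed = [
        TemporalDiagnosis(ROLE_TO_TIMING[r], c)
        for r, c in zip(merged["visit_role"], merged["code"])
    ]
    if vocabulary is None:
        vocab = canonical_order(observed)
    else:
        vocab = canonical_order(vocabulary)

    patient_ids = tables.patients["patient_id"].tolist()
    col_of = {td: j for j, td in enumerate(vocab)}
    row_of = {pid: i for i, pid in enumerate(patient_ids)}
    values = np.zeros((len(patient_ids), len(vocab)), dtype=np.uint8)
    for pid, td in zip(merged["patient_id"], observed):
        j = col_of.get(td)
        if j is not None and pid in row_of:
            values[row_of[pid], j] = 1
    data = pd.DataFrame(
        values, index=pd.Index(patient_ids, name="patient_id"), columns=[t.render() for t in vocab]
    )
    return FeatureMatrix(data, vocab)


def classify_race(race: str | None, ethnicity: str | None) -> str:
    """Race/ethnicity → analysis category.

    Hispanic/Latino ethnicity dominates any recorded race; both fields missing
    means Unknown; recognized race values pass through; anything else maps to
    Heterogeneous Other (and is logged once per value).
    """
    race = race if race and not pd.isna(race) else None
    ethnicity = ethnicity if ethnicity and not pd.isna(ethnicity) else None
    if ethnicity in HISPANIC_ETHNICITIES:
        return "Hispanic"
    if race is None:
        return "Unknown"
    if race in RACE_PASSTHROUGH:
        return RACE_PASSTHROUGH[race]
    logger.debug("unrecognized race value %r -> Heterogeneous Other", race)
    return "Heterogeneous Other"


def _payers(insurance_field: str | float) -> list[str]:
    if insurance_field is None or (isinstance(insurance_field, float) and np.isnan(insurance_field)):
        return []
    text = str(insurance_field).strip()
    return [p for p in text.split("|") if p] if text else []


def classify_medicaid(
    patient_visits: pd.DataFrame, window_days: int = 365, two_sided: bool = True
) -> bool | str:
    """Medicaid/CHIP enrollment at (or within a year of) the index visit.

    The index visit's payer list decides when non-empty. When it is empty, all
    visits within ``window_days`` of the index visit are scanned (both
    directions by default): any Medicaid/CHIP record → enrolled; any other
    payer → not enrolled; no payer anywhere in the window → :data:`DROPPED`.
    """
    idx = patient_visits[patient_visits["visit_role"] == "index"]
    if len(idx) != 1:
        raise ValueError("patient must have exactly one index visit")
    index_day = int(idx["day_offset"].iloc[0])
    index_payers = _payers(idx["insurance"].iloc[0])
    if index_payers:
        return any(p in MEDICAID_PAYERS for p in index_payers)

    delta = patient_visits["day_offset"].astype(int) - index_day
    in_window = (delta.abs() <= window_days) if two_sided else (delta.between(0, window_days))
    window_payers: list[str] = []
    for ins in patient_visits.loc[in_window, "insurance"]:
        window_payers.extend(_payers(ins))
    if any(p in MEDICAID_PAYERS for p in window_payers):
        return True
    if window_payers:
        return False
    return DROPPED


def categorize_age(age_at_index: float) -> str:
    """Exact age in years → category, with half-open bins [2,5), [5,12), [12,19)."""
    if not (2 <= age_at_index < 19):
        raise ValueError(f"age at index must be in [2, 19), got {age_at_index}")
    if age_at_index < 5:
        return "2-4"
    if age_at_index < 12:
        return "5-11"
    return "12-18"


def build_demographics(
    tables: CohortTables, window_days: int = 365, two_sided: bool = True
) -> tuple[pd.DataFrame, CohortTables]:
    """Per-patient demographics table; patients with no insurance information
    within the window are dropped from the returned tables and logged.

    Returns (demographics, tables-after-drops). Demographics columns: sex,
    race_category, medicaid_enrolled, age_at_index, age_category,
    philadelphia_resident.
    """
    visits_by_patient = {pid: grp for pid, grp in tables.visits.groupby("patient_id", sort=False)}
    rows = []
    dropped: list[tuple[str, str]] = []
    for rec in tables.patients.itertuples(index=False):
        pid = rec.patient_id
        enrolled = classify_medicaid(visits_by_patient[pid], window_days, two_sided)
        if enrolled == DROPPED:
            dropped.append((pid, EXCLUSION_NO_INSURANCE))
            continue
        age = -float(rec.birth_offset_days) / DAYS_PER_YEAR
        rows.append(
            {
                "patient_id": pid,
                "sex": rec.sex,
                "race_category": classify_race(rec.race, rec.ethnicity),
                "medicaid_enrolled": bool(enrolled),
                "age_at_index": age,
                "age_category": categorize_age(age),
                "philadelphia_resident": bool(rec.philadelphia_resident),
            }
        )
    demographics = pd.DataFrame(rows)
    dropped_ids = {pid for pid, _ in dropped}
    out = tables
    if dropped_ids:
        logger.info("dropped %d patients with no insurance within a year", len(dropped_ids))
        # also drop match partners so pairs stay total
        partners = {tables.match_pairs[c] for c in dropped_ids if c in tables.match_pairs}
        partners |= {c for c, t in tables.match_pairs.items() if t in dropped_ids}
        partners -= dropped_ids
        dropped.extend((pid, EXCLUSION_PARTNER) for pid in sorted(partners))
        keep = set(tables.patients["patient_id"]) - dropped_ids - partners
        out = tables.subset(keep)
        demographics = demographics[demographics["patient_id"].isin(keep)].reset_index(drop=True)
    out = replace(
        out,
        exclusions=pd.concat(
            [out.exclusions, pd.DataFrame(dropped, columns=["patient_id", "reason"])],
            ignore_index=True,
        ),
    )
    return demographics, out


def write_features(features: FeatureMatrix, path) -> None:
    features.data.to_csv(path)


def read_features(path) -> FeatureMatrix:
    data = pd.read_csv(path, index_col="patient_id")
    vocab = [TemporalDiagnosis.parse(c) for c in data.columns]
    return FeatureMatrix(data.astype(np.uint8), vocab)


def prior_visit_count(patient_visits: pd.DataFrame) -> int:
    """Number of visits strictly before the index visit (the matching covariate)."""
    idx = patient_visits[patient_visits["visit_role"] == "index"]
    if len(idx) != 1:
        raise ValueError("patient must have exactly one index visit")
    index_day = int(idx["day_offset"].iloc[0])
    index_vid = idx["visit_id"].iloc[0]
    earlier = patient_visits[
        (patient_visits["day_offset"] < index_day)
        | ((patient_visits["day_offset"] == index_day) & (patient_visits["visit_id"] < index_vid))
    ]
    return int(len(earlier))
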