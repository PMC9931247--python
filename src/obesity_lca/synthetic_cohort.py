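"""Synthetic EHR-like case/control cohorts with known latent class structure.

Real pediatric EHR data of this kind cannot be shared, so this module
generates cohorts with the same relational shape (patients, visits,
diagnoses) and a *known* ground truth: each case patient belongs to one of
``k_true`` latent comorbidity classes, and given the class their timing-tagged
diagnoses are independent Bernoulli draws. That product-Bernoulli-within-class
structure is exactly what the downstream latent class model assumes, which is
what makes parameter-recovery testing possible.

Case visit structure: every case has a pre-index visit without an obese BMI,
an index visit with the first obese BMI, optionally 0-2 earlier "other"
visits, and a post-index visit with probability ``post_index_prob`` (default
0.676). Timing-3 (post-index) diagnoses are only emitted when the post-index
visit exists, so their marginal prevalence is deflated by the post-index
probability relative to the class-conditional draw probability.

Controls are synthesized 1:1 per case, exactly matched on sex, age category
and prior-visit count (they reuse the case's visit skeleton), never obese,
with feature prevalences equal to the case marginals deflated by
``control_odds_ratio`` on the odds scale.

Visit "dates" are integer day offsets from the index visit — PHI-free and
sufficient for the one-year insurance window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import default_profiles as defaults
from .cohort_builder import (
    DAYS_PER_YEAR,
    DIAGNOSIS_COLUMNS,
    PATIENT_COLUMNS,
    VISIT_COLUMNS,
    CohortTables,
    build_temporal_features,
    categorize_age,
)
from .temporal import TIMING_POST, TemporalDiagnosis

AGE_MIN, AGE_MAX = 2.0, 19.0


class ConfigurationError(ValueError):
    """Raised when generator settings violate their invariants."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``item_probs`` has shape (k_true, J) where J = len(vocabulary);
    ``demographic_params`` holds one dict per class (see
    :func:`obesity_lca.default_profiles.default_demographic_params` for keys).
    ``control_odds_ratio`` deflates each feature's case marginal prevalence on
    the odds scale to obtain the control prevalence.
    """

    n_cases: int = 3000
    k_true: int = 8
    mixing_weights: np.ndarray = field(
        default_factory=lambda: defaults.DEFAULT_MIXING_WEIGHTS.copy()
    )
    item_probs: np.ndarray = field(default_factory=lambda: defaults.DEFAULT_ITEM_PROBS.copy())
    vocabulary: list[TemporalDiagnosis] = field(
        default_factory=lambda: list(defaults.DEFAULT_VOCABULARY)
    )
    control_odds_ratio: float = 2.0
    post_index_prob: float = defaults.DEFAULT_POST_INDEX_PROB
    demographic_params: list[dict] = field(
        default_factory=defaults.default_demographic_params
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        self.item_probs = np.asarray(self.item_probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_cases <= 0 or self.k_true <= 0:
            raise ConfigurationError("n_cases and k_true must be positive")
        if self.mixing_weights.shape != (self.k_true,):
            raise ConfigurationError("mixing_weights must have length k_true")
        if abs(self.mixing_weights.sum() - 1.0) > 1e-9 or (self.mixing_weights <= 0).any():
            raise ConfigurationError("mixing_weights must be positive and sum to 1")
        if self.item_probs.shape != (self.k_true, len(self.vocabulary)):
            raise ConfigurationError("item_probs must be k_true x len(vocabulary)")
        if ((self.item_probs < 0) | (self.item_probs > 1)).any():
            raise ConfigurationError("item_probs entries must be in [0, 1]")
        if not (0 <= self.post_index_prob <= 1):
            raise ConfigurationError("post_index_prob must be in [0, 1]")
        if self.control_odds_ratio <= 0:
            raise ConfigurationError("control_odds_ratio must be positive")
        if len(self.demographic_params) != self.k_true:
            raise ConfigurationError("demographic_params must have one entry per class")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "k_true": self.k_true,
            "mixing_weights": self.mixing_weights.tolist(),
            "item_probs": self.item_probs.tolist(),
            "vocabulary": [t.render() for t in self.vocabulary],
            "control_odds_ratio": self.control_odds_ratio,
            "post_index_prob": self.post_index_prob,
            "demographic_params": self.demographic_params,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "vocabulary" in d:
            d["vocabulary"] = [TemporalDiagnosis.parse(t) for t in d["vocabulary"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """True class of every generated case patient, plus the config that made them."""

    class_of_patient: dict[str, int]
    config_echo: GeneratorConfig


def _truncnorm_ages(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    a, b = (AGE_MIN - mean) / sd, (AGE_MAX - mean) / sd
    ages = truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    # keep half a day of rounding headroom at both bin edges
    return np.clip(ages, AGE_MIN + 0.002, AGE_MAX - 0.002)


_HISPANIC_BASE_RACES = ["White", "Black/African American", ""]
_HISPANIC_BASE_PROBS = [0.6, 0.3, 0.1]


def _race_fields(rng: np.random.Generator, category: str) -> tuple[str, str]:
    """Map an analysis race category back to raw (race, ethnicity) strings."""
    if category == "Hispanic":
        race = rng.choice(_HISPANIC_BASE_RACES, p=_HISPANIC_BASE_PROBS)
        return str(race), "Hispanic or Latino"
    if category == "Unknown":
        return "", ""
    if category == "Heterogeneous Other":
        return "Some Other Race", "Not Hispanic or Latino"
    return category, "Not Hispanic or Latino"


def _visit_insurance(
    rng: np.random.Generator, primary: str, no_insurance: bool, recorded_prob: float = 0.7
) -> str:
    if no_insurance:
        return ""
    return primary if rng.random() < recorded_prob else ""


def generate_cases(config: GeneratorConfig) -> tuple[CohortTables, GroundTruth]:
    """Generate the case cohort and its ground-truth class assignments."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, k, vocab = config.n_cases, config.k_true, config.vocabulary
    J = len(vocab)
    timing3 = np.array([t.timing == TIMING_POST for t in vocab])

    classes = rng.choice(k, size=n, p=config.mixing_weights)
    has_post = rng.random(n) < config.post_index_prob
    presence = rng.random((n, J)) < config.item_probs[classes]
    presence[~has_post[:, None] & timing3[None, :]] = False

    params = config.demographic_params
    male_p = np.array([p["male_prob"] for p in params])
    medicaid_p = np.array([p["medicaid_prob"] for p in params])
    phila_p = np.array([p["philadelphia_prob"] for p in params])
    missing_idx_p = np.array([p["missing_index_insurance_prob"] for p in params])
    no_ins_p = np.array([p["no_insurance_prob"] for p in params])

    male = rng.random(n) < male_p[classes]
    medicaid = rng.random(n) < medicaid_p[classes]
    phila = rng.random(n) < phila_p[classes]
    missing_index_ins = rng.random(n) < missing_idx_p[classes]
    no_insurance = rng.random(n) < no_ins_p[classes]
    chip = rng.random(n) < 0.15  # Medicaid patients carry CHIP instead ~15% of the time
    dual = rng.random(n) < 0.10  # Medicaid patients with a second, commercial payer

    ages = np.empty(n)
    race_cat = np.empty(n, dtype=object)
    for kk in range(k):
        mask = classes == kk
        m = int(mask.sum())
        if m == 0:
            continue
        ages[mask] = _truncnorm_ages(rng, params[kk]["age_mean"], params[kk]["age_sd"], m)
        race_cat[mask] = rng.choice(
            defaults.RACE_CATEGORIES, size=m, p=np.asarray(params[kk]["race_probs"])
        )

    patient_rows, visit_rows, dx_rows = [], [], []
    class_of_patient: dict[str, int] = {}
    for i in range(n):
        pid = f"case-{i:06d}"
        class_of_patient[pid] = int(classes[i])
        race, ethnicity = _race_fields(rng, race_cat[i])
        patient_rows.append(
            (
                pid,
                "case",
                pid,
                "Male" if male[i] else "Female",
                race,
                ethnicity,
                int(phila[i]),
                -int(round(ages[i] * DAYS_PER_YEAR)),
            )
        )

        primary = ("CHIP" if chip[i] else "Medicaid") if medicaid[i] else "Commercial"
        if medicaid[i] and dual[i]:
            primary = primary + "|Commercial"

        n_extra = int(rng.integers(0, 3))
        pre_day = -int(rng.integers(30, 365))
        days_roles = [(pre_day, "pre", 0)]
        day = pre_day
        for _ in range(n_extra):
            day -= int(rng.integers(60, 300))
            days_roles.append((day, "other", 0))
        days_roles.append((0, "index", 1))
        if has_post[i]:
            days_roles.append((int(rng.integers(30, 365)), "post", 1))
        days_roles.sort(key=lambda t: t[0])

        role_visit: dict[str, str] = {}
        for j, (day, role, obese) in enumerate(days_roles):
            vid = f"{pid}-v{j}"
            if role == "index":
                ins = "" if missing_index_ins[i] else ("" if no_insurance[i] else primary)
            else:
                ins = _visit_insurance(rng, primary, no_insurance[i])
            visit_rows.append((vid, pid, role, day, obese, ins))
            role_visit[role] = vid

        for j in np.nonzero(presence[i])[0]:
            td = vocab[j]
            role = {1: "pre", 2: "index", 3: "post"}[td.timing]
            dx_rows.append((role_visit[role], td.code))

    tables = CohortTables(
        patients=pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS),
        visits=pd.DataFrame(visit_rows, columns=VISIT_COLUMNS),
        diagnoses=pd.DataFrame(dx_rows, columns=DIAGNOSIS_COLUMNS),
    )
    return tables, GroundTruth(class_of_patient, config)


def deflate_prevalence(prevalence: np.ndarray, odds_ratio: float) -> np.ndarray:
    """Deflate a prevalence by an odds ratio: p → odds⁻¹(odds(p) / OR).

    Endpoints 0 and 1 are fixed points.
    """
    p = np.asarray(prevalence, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = p / (1.0 - p) / odds_ratio
        out = odds / (1.0 + odds)
    return np.where(p >= 1.0, 1.0, np.where(p <= 0.0, 0.0, out))


def generate_matched_controls(cases: CohortTables, config: GeneratorConfig) -> CohortTables:
    """Synthesize one healthy-BMI control per case, exactly matched on sex,
    age category and prior-visit count.

    Controls reuse the matched case's visit skeleton (same day offsets, same
    presence of the post-index reference visit) with every obese flag false;
    feature prevalences are the empirical case marginals deflated by
    ``control_odds_ratio`` on the odds scale. Demographics other than the
    matching variables are drawn from the class-mixture marginal distributions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    vocab = config.vocabulary
    J = len(vocab)
    timing3 = np.array([t.timing == TIMING_POST for t in vocab])

    fm = build_temporal_features(cases, vocab)
    case_ids = fm.patient_ids
    n = len(case_ids)
    marginal = fm.data.to_numpy().mean(axis=0)
    target = deflate_prevalence(marginal, config.control_odds_ratio)

    case_visits = {pid: grp for pid, grp in cases.visits.groupby("patient_id", sort=False)}
    has_post = np.array(
        [(case_visits[pid]["visit_role"] == "post").any() for pid in case_ids]
    )
    n_eligible = max(int(has_post.sum()), 1)
    # timing-3 items can only appear on controls whose skeleton has a post
    # visit; rescale so the overall control marginal still hits the target
    draw_prob = np.where(timing3, np.minimum(1.0, target * n / n_eligible), target)
    presence = rng.random((n, J)) < draw_prob[None, :]
    presence[~has_post[:, None] & timing3[None, :]] = False

    w = config.mixing_weights
    params = config.demographic_params
    race_marg = np.sum(
        [w[kk] * np.asarray(params[kk]["race_probs"]) for kk in range(config.k_true)], axis=0
    )
    race_marg = race_marg / race_marg.sum()
    medicaid_marg = float(np.dot(w, [p["medicaid_prob"] for p in params]))
    phila_marg = float(np.dot(w, [p["philadelphia_prob"] for p in params]))
    missing_idx_marg = float(np.dot(w, [p["missing_index_insurance_prob"] for p in params]))
    no_ins_marg = float(np.dot(w, [p["no_insurance_prob"] for p in params]))

    case_patients = cases.patients.set_index("patient_id")
    patient_rows, visit_rows, dx_rows = [], [], []
    match_pairs: dict[str, str] = {}
    for i, case_id in enumerate(case_ids):
        pid = f"ctrl-{i:06d}"
        match_pairs[case_id] = pid
        case_rec = case_patients.loc[case_id]
        race, ethnicity = _race_fields(rng, rng.choice(defaults.RACE_CATEGORIES, p=race_marg))
        patient_rows.append(
            (
                pid,
                "control",
                case_id,
                case_rec["sex"],
                race,
                ethnicity,
                int(rng.random() < phila_marg),
                int(case_rec["birth_offset_days"]),
            )
        )

        medicaid = rng.random() < medicaid_marg
        no_insurance = rng.random() < no_ins_marg
        missing_index_ins = rng.random() < missing_idx_marg
        primary = ("CHIP" if rng.random() < 0.15 else "Medicaid") if medicaid else "Commercial"

        skeleton = case_visits[case_id].sort_values(["day_offset", "visit_id"], kind="mergesort")
        role_visit: dict[str, str] = {}
        for j, (_, v) in enumerate(skeleton.iterrows()):
            vid = f"{pid}-v{j}"
            role = v["visit_role"]
            if role == "index":
                ins = "" if (missing_index_ins or no_insurance) else primary
            else:
                ins = _visit_insurance(rng, primary, no_insurance)
            visit_rows.append((vid, pid, role, int(v["day_offset"]), 0, ins))
            role_visit[role] = vid

        for j in np.nonzero(presence[i])[0]:
            td = vocab[j]
            role = {1: "pre", 2: "index", 3: "post"}[td.timing]
            dx_rows.append((role_visit[role], td.code))

    return CohortTables(
        patients=pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS),
        visits=pd.DataFrame(visit_rows, columns=VISIT_COLUMNS),
        diagnoses=pd.DataFrame(dx_rows, columns=DIAGNOSIS_COLUMNS),
        match_pairs=match_pairs,
    )


def combine_cohorts(cases: CohortTables, controls: CohortTables) -> CohortTables:
    """Stack case and control tables into one cohort, keeping the match pairs."""
    return CohortTables(
        patients=pd.concat([cases.patients, controls.patients], ignore_index=True),
        visits=pd.concat([cases.visits, controls.visits], ignore_index=True),
        diagnoses=pd.concat([cases.diagnoses, controls.diagnoses], ignore_index=True),
        match_pairs=dict(controls.match_pairs),
        exclusions=pd.concat([cases.exclusions, controls.exclusions], ignore_index=True),
    )


# -- disk round trip ---------------------------------------------------------

def write_cohort(tables: CohortTables, outdir: str | Path) -> None:
    """Write patients/visits/diagnoses (+ match pairs, exclusions) as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables.patients.to_csv(outdir / "patients.csv", index=False)
    tables.visits.to_csv(outdir / "visits.csv", index=False)
    tables.diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
    pd.DataFrame(
        sorted(tables.match_pairs.items()), columns=["case_id", "control_id"]
    ).to_csv(outdir / "match_pairs.csv", index=False)
    tables.exclusions.to_csv(outdir / "exclusions.csv", index=False)


def read_cohort(indir: str | Path) -> CohortTables:
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.csv", keep_default_na=False, dtype={"race": str, "ethnicity": str})
    visits = pd.read_csv(indir / "visits.csv", keep_default_na=False, dtype={"insurance": str})
    visits["day_offset"] = visits["day_offset"].astype(int)
    visits["obese_flag"] = visits["obese_flag"].astype(int)
    diagnoses = pd.read_csv(indir / "diagnoses.csv", keep_default_na=False)
    pairs_path = indir / "match_pairs.csv"
    match_pairs = {}
    if pairs_path.exists():
        mp = pd.read_csv(pairs_path, keep_default_na=False)
        match_pairs = dict(zip(mp["case_id"], mp["control_id"]))
    excl_path = indir / "exclusions.csv"
    exclusions = (
        pd.read_csv(excl_path, keep_default_na=False)
        if excl_path.exists()
        else pd.DataFrame(columns=["patient_id", "reason"])
    )
    return CohortTables(patients, visits, diagnoses, match_pairs, exclusions)


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(truth.class_of_patient.items()), columns=["patient_id", "true_class"]
    ).to_csv(outdir / "ground_truth.csv", index=False)
    truth.config_echo.to_yaml(outdir / "generator_config.yaml")
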