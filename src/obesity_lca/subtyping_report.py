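"""Clinical and demographic characterization of the fitted patient subtypes.

Each latent class is described by the prevalence of every temporal diagnosis
among its assigned patients. Features at or above the high-prevalence
threshold (default 10%) name the subtype; a class in which no feature reaches
the characterization floor (default 5%) is labelled as having no
characteristic morbidity pattern. Demographic tables report counts and
percents of sex, race category, Medicaid enrollment, age category and urban
residence, plus mean (SD) age, overall and per class. Both thresholds are
inclusive (≥).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_builder import AGE_CATEGORIES, FeatureMatrix
from .lca import PosteriorMatrix, membership_summary
from .temporal import TemporalDiagnosis

UNCHARACTERIZED_LABEL = "Other - no characteristic morbidity pattern"

HIGH_PREVALENCE_THRESHOLD = 10.0  # percent
CHARACTERIZATION_FLOOR = 5.0  # percent


@dataclass
class SubtypeProfile:
    class_id: int
    n_assigned: int
    feature_prevalence: dict[TemporalDiagnosis, float]  # percent
    high_prevalence_set: list[TemporalDiagnosis] = field(default_factory=list)
    label: str = ""
    is_uncharacterized: bool = False


def class_prevalence(
    features: FeatureMatrix, assignments: np.ndarray, n_classes: int | None = None
) -> pd.DataFrame:
    """Percent prevalence of every feature within every assigned class.

    Rows are features (rendered), columns are class ids; an empty class gives
    a NaN column and a logged warning rather than an error. Values are raw
    percents; round to 2 decimals for display.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(features.data):
        raise ValueError("one assignment per patient required")
    K = n_classes or (int(assignments.max()) + 1 if len(assignments) else 0)
    arr = features.data.to_numpy()
    cols = {}
    for g in range(K):
        members = arr[assignments == g]
        cols[g] = members.mean(axis=0) * 100.0 if len(members) else np.full(arr.shape[1], np.nan)
    return pd.DataFrame(cols, index=features.data.columns)


def characterize_class(
    class_id: int,
    prevalence: pd.Series,
    n_assigned: int,
    high_prev_threshold: float = HIGH_PREVALENCE_THRESHOLD,
    floor: float = CHARACTERIZATION_FLOOR,
    label_override: str | None = None,
    max_label_features: int = 5,
) -> SubtypeProfile:
    """Build a labelled profile for one class from its prevalence column.

    ``prevalence`` is indexed by rendered feature strings, in percent. The
    auto-generated label joins the most prevalent high-prevalence features
    (clinical naming is ultimately editorial, so overrides are supported).
    """
    feats = {TemporalDiagnosis.parse(k): float(v) for k, v in prevalence.items()}
    high = [td for td, p in feats.items() if p >= high_prev_threshold]
    high.sort(key=lambda td: (-feats[td], td.sort_key))
    uncharacterized = not any(p >= floor for p in feats.values())
    if label_override is not None:
        label = label_override
    elif uncharacterized:
        label = UNCHARACTERIZED_LABEL
    else:
        named = high if high else sorted(feats, key=lambda td: (-feats[td], td.sort_key))[:1]
        label = "; ".join(
            f"{td.render()} ({feats[td]:.2f}%)" for td in named[:max_label_features]
        )
    return SubtypeProfile(
        class_id=class_id,
        n_assigned=n_assigned,
        feature_prevalence=feats,
        high_prevalence_set=high,
        label=label,
        is_uncharacterized=uncharacterized,
    )


def characterize_all(
    features: FeatureMatrix,
    assignments: np.ndarray,
    high_prev_threshold: float = HIGH_PREVALENCE_THRESHOLD,
    floor: float = CHARACTERIZATION_FLOOR,
    label_overrides: dict[int, str] | None = None,
) -> list[SubtypeProfile]:
    prev = class_prevalence(features, assignments)
    overrides = label_overrides or {}
    sizes = np.bincount(np.asarray(assignments), minlength=prev.shape[1])
    return [
        characterize_class(
            g,
            prev[g].fillna(0.0),
            int(sizes[g]),
            high_prev_threshold,
            floor,
            overrides.get(g),
        )
        for g in prev.columns
    ]


_CATEGORICALS = [
    ("sex", ["Male", "Female"]),
    (
        "race_category",
        [
            "Asian",
            "Black/African American",
            "White",
            "Hispanic",
            "Multiple Race",
            "Heterogeneous Other",
            "Unknown",
        ],
    ),
    ("medicaid_enrolled", [True]),
    ("age_category", AGE_CATEGORIES),
    ("philadelphia_resident", [True]),
]


def _summarize_one(demo: pd.DataFrame) -> list[dict]:
    n = len(demo)
    rows = []
    for var, levels in _CATEGORICALS:
        for level in levels:
            count = int((demo[var] == level).sum())
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    "n": count,
                    "pct": round(100.0 * count / n, 1) if n else np.nan,
                }
            )
    age = demo["age_at_index"]
    rows.append(
        {
            "variable": "age_at_index",
            "level": "mean_sd",
            "n": n,
            "pct": np.nan,
            "mean": round(float(age.mean()), 1) if n else np.nan,
            "sd": round(float(age.std(ddof=0)), 1) if n else np.nan,
        }
    )
    return rows


def demographic_summary(
    demographics: pd.DataFrame, assignments: pd.Series | None = None
) -> pd.DataFrame:
    """Counts and percents of every demographic variable, overall and per class.

    ``assignments`` maps patient_id → class (any ordering); when omitted only
    the overall column is produced. Percent denominators are class sizes; age
    is summarized as mean (SD) in years. Tidy output: one row per
    (group, variable, level).
    """
    frames = []
    overall = pd.DataFrame(_summarize_one(demographics))
    overall.insert(0, "group", "overall")
    frames.append(overall)
    if assignments is not None:
        assigned = demographics.merge(
            assignments.rename("assigned_class"),
            left_on="patient_id",
            right_index=True,
            how="inner",
        )
        for g, grp in assigned.groupby("assigned_class", sort=True):
            block = pd.DataFrame(_summarize_one(grp))
            block.insert(0, "group", f"class_{g}")
            frames.append(block)
    return pd.concat(frames, ignore_index=True)


# -- report assembly ---------------------------------------------------------

def profiles_to_frame(profiles: list[SubtypeProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": p.class_id,
                "n_assigned": p.n_assigned,
                "label": p.label,
                "is_uncharacterized": int(p.is_uncharacterized),
                "high_prevalence_features": ";".join(t.render() for t in p.high_prevalence_set),
            }
            for p in profiles
        ]
    )


def write_report(
    outdir: str | Path,
    ic_table: pd.DataFrame,
    features: FeatureMatrix,
    posterior: PosteriorMatrix,
    profiles: list[SubtypeProfile],
    demographics: pd.DataFrame,
) -> None:
    """Write the CSV analogues of the study tables plus one markdown digest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assignments = posterior.assigned_class

    prev = class_prevalence(features, assignments).round(2)
    prev.index.name = "feature"
    prev.to_csv(outdir / "subtype_prevalence.csv", float_format="%.2f")

    profiles_to_frame(profiles).to_csv(outdir / "subtype_labels.csv", index=False)

    mean_df, sd_df, _ = membership_summary(posterior)
    mm = mean_df.round(2).astype(str) + " (" + sd_df.round(2).astype(str) + ")"
    mm.to_csv(outdir / "membership_matrix.csv")

    summary = demographic_summary(
        demographics, pd.Series(assignments, index=posterior.patient_ids)
    )
    summary.to_csv(outdir / "demographics_by_class.csv", index=False, float_format="%.10g")

    lines = ["# Subtype report", "", "## Model comparison", "", ic_table.to_markdown(index=False), ""]
    lines += ["## Subtype labels", "", profiles_to_frame(profiles).to_markdown(index=False), ""]
    lines += ["## Mean posterior membership (%) by assigned class", "", mm.to_markdown(), ""]
    lines += [
        "## Demographics (overall)",
        "",
        summary[summary["group"] == "overall"].to_markdown(index=False),
        "",
    ]
    (outdir / "report.md").write_text("\n".join(lines))
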