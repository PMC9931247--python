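"""End-to-end orchestration: simulate → build → mine → test → fit → characterize.

Every stage reads its inputs from, and writes its outputs to, CSV files under
the run directory, so any stage can be re-run independently from the previous
stage's on-disk outputs. One master seed derives fixed per-stage child seeds;
identical configuration and seed produce byte-identical outputs. A run
manifest records configuration, seed and the row counts flowing through each
stage (inputs = retained + excluded at every step).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort_builder import (
    CohortTables,
    build_demographics,
    build_temporal_features,
    identify_index_visits,
    read_features,
    write_features,
)
from .lca import derive_seed, sweep_models, write_sweep, PosteriorMatrix
from .pattern_mining import (
    MiningConfig,
    frequent_subsequences,
    mine_frequent_patterns,
    read_patterns,
    write_patterns,
)
from .pattern_stats import results_to_frame, select_significant, compare_patterns
from .subtyping_report import characterize_all, write_report
from .synthetic_cohort import (
    GeneratorConfig,
    combine_cohorts,
    generate_cases,
    generate_matched_controls,
    read_cohort,
    write_cohort,
    write_ground_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage settings in one place; defaults follow the study conditions."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_support: float = 0.01
    alpha: float = 0.05
    adjust: str = "none"
    correction: bool = True
    k_min: int = 3
    k_max: int = 8
    n_starts: int = 20
    max_iter: int = 5000
    tol: float = 1e-8
    high_prev_threshold: float = 10.0
    floor: float = 5.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig.from_dict(raw.pop("generator", {}))
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    gen = config.generator
    # re-key the generator on the master seed so one seed drives the whole run
    gen = GeneratorConfig.from_dict({**gen.to_dict(), "seed": derive_seed(config.seed, 1)})
    cases, truth = generate_cases(gen)
    controls = generate_matched_controls(cases, gen)
    cohort = combine_cohorts(cases, controls)
    write_cohort(cohort, outdir / "cohort")
    write_ground_truth(truth, outdir / "cohort")
    return {
        "n_cases_generated": len(cases.patients),
        "n_controls_generated": len(controls.patients),
    }


def stage_build(config: PipelineConfig, outdir: Path) -> dict:  # noqa: ARG001 - uniform stage signature
    cohort = read_cohort(outdir / "cohort")
    n_in = len(cohort.patients)
    cohort = identify_index_visits(cohort)
    demographics, cohort = build_demographics(cohort)
    features = build_temporal_features(cohort)
    build_dir = outdir / "build"
    build_dir.mkdir(parents=True, exist_ok=True)
    write_features(features, build_dir / "features.csv")
    demographics.to_csv(build_dir / "demographics.csv", index=False, float_format="%.10g")
    cohort.exclusions.to_csv(build_dir / "exclusions.csv", index=False)
    pd.DataFrame(
        sorted(cohort.match_pairs.items()), columns=["case_id", "control_id"]
    ).to_csv(build_dir / "match_pairs.csv", index=False)
    cohort.patients[["patient_id", "cohort"]].to_csv(build_dir / "cohorts.csv", index=False)
    n_excluded = len(cohort.exclusions)
    return {
        "n_patients_in": n_in,
        "n_patients_retained": len(cohort.patients),
        "n_patients_excluded": n_excluded,
        "n_pairs": len(cohort.match_pairs),
    }


def _load_build(outdir: Path):
    build_dir = outdir / "build"
    features = read_features(build_dir / "features.csv")
    cohorts = pd.read_csv(build_dir / "cohorts.csv")
    mp = pd.read_csv(build_dir / "match_pairs.csv")
    match_pairs = dict(zip(mp["case_id"], mp["control_id"]))
    case_ids = cohorts.loc[cohorts["cohort"] == "case", "patient_id"].tolist()
    control_ids = cohorts.loc[cohorts["cohort"] == "control", "patient_id"].tolist()
    from .cohort_builder import FeatureMatrix

    case_fm = FeatureMatrix(features.data.loc[case_ids], features.vocabulary)
    control_fm = FeatureMatrix(features.data.loc[control_ids], features.vocabulary)
    return case_fm, control_fm, match_pairs


def stage_mine(config: PipelineConfig, outdir: Path) -> dict:
    case_fm, _, _ = _load_build(outdir)
    patterns = mine_frequent_patterns(case_fm, MiningConfig(min_support=config.min_support))
    write_patterns(patterns, len(case_fm.data), outdir / "patterns.csv")
    return {"n_patterns_mined": len(patterns)}


def stage_test(config: PipelineConfig, outdir: Path) -> dict:
    case_fm, control_fm, match_pairs = _load_build(outdir)
    patterns = read_patterns(outdir / "patterns.csv")
    results = compare_patterns(
        patterns,
        case_fm,
        control_fm,
        match_pairs,
        alpha=config.alpha,
        adjust=config.adjust,
        correction=config.correction,
    )
    results_to_frame(results).to_csv(outdir / "mcnemar.csv", index=False, float_format="%.10g")
    significant = select_significant(results)
    vocabulary = frequent_subsequences([r.pattern for r in significant])
    pd.DataFrame({"feature": [t.render() for t in vocabulary]}).to_csv(
        outdir / "selected_features.csv", index=False
    )
    return {
        "n_patterns_tested": len(results),
        "n_patterns_significant": len(significant),
        "n_features_selected": len(vocabulary),
    }


def stage_fit(config: PipelineConfig, outdir: Path) -> dict:
    case_fm, _, _ = _load_build(outdir)
    selected = pd.read_csv(outdir / "selected_features.csv")["feature"].tolist()
    if not selected:
        logger.warning("no features selected; skipping latent class fitting")
        return {"n_features_fit": 0, "lca_skipped": 1}
    from .cohort_builder import FeatureMatrix
    from .temporal import TemporalDiagnosis

    vocab = [TemporalDiagnosis.parse(c) for c in selected]
    fm = FeatureMatrix(case_fm.data[selected], vocab)
    sweep = sweep_models(
        fm,
        k_min=config.k_min,
        k_max=config.k_max,
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=derive_seed(config.seed, 2),
    )
    write_sweep(sweep, outdir / "lca")
    write_features(fm, outdir / "lca" / "lca_features.csv")
    return {
        "n_patients_fit": len(fm.data),
        "n_features_fit": len(vocab),
        "selected_K": sweep.selected_K,
    }


def stage_characterize(config: PipelineConfig, outdir: Path) -> dict:
    lca_dir = outdir / "lca"
    if not (lca_dir / "posteriors.csv").exists():
        logger.warning("no fitted model found; nothing to characterize")
        return {"n_profiles": 0}
    fm = read_features(lca_dir / "lca_features.csv")
    post_df = pd.read_csv(lca_dir / "posteriors.csv")
    tau_cols = [c for c in post_df.columns if c.startswith("tau_")]
    posterior = PosteriorMatrix(
        post_df[tau_cols].to_numpy(), post_df["patient_id"].tolist()
    )
    assignments = posterior.assigned_class
    profiles = characterize_all(
        fm, assignments, config.high_prev_threshold, config.floor
    )
    demographics = pd.read_csv(outdir / "build" / "demographics.csv")
    demographics = demographics[demographics["patient_id"].isin(set(posterior.patient_ids))]
    models = pd.read_csv(lca_dir / "lca_models.csv")
    write_report(outdir / "report", models, fm, posterior, profiles, demographics)
    return {"n_profiles": len(profiles)}


STAGES = [
    ("simulate", stage_simulate),
    ("build", stage_build),
    ("mine", stage_mine),
    ("test", stage_test),
    ("fit-lca", stage_fit),
    ("characterize", stage_characterize),
]


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    for name, fn in STAGES:
        try:
            counts = fn(config, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            _write_manifest(manifest, outdir)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
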