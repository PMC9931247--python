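"""Reference simulation scenarios for validating the pipeline.

These are fixed, documented study conditions used by the test suite and the
reproduction script:

* :func:`recovery_config` — a three-class cohort with well-separated
  class-conditional probabilities over a 12-item pre/index vocabulary, used
  for parameter-recovery studies (can the fitted model get π and ρ back, and
  does BIC pick the true class count?). The vocabulary deliberately contains
  no post-index items: post-index diagnoses are marginally deflated by the
  post-index visit probability, so they estimate 0.676·ρ rather than ρ and
  would confound a recovery measurement.
* :func:`match_permutation` — best label alignment between a fitted model and
  the generating truth (latent class labels are only identified up to
  permutation).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .synthetic_cohort import GeneratorConfig
from .temporal import TemporalDiagnosis

RECOVERY_MIXING = (0.5, 0.3, 0.2)
RECOVERY_HIGH, RECOVERY_LOW = 0.8, 0.1


def simple_demographics(k: int) -> list[dict]:
    """Flat, class-independent demographic parameters for scenarios where
    demographics are not under study."""
    return [
        {
            "male_prob": 0.55,
            "race_probs": [0.02, 0.34, 0.47, 0.09, 0.01, 0.005, 0.065],
            "medicaid_prob": 0.41,
            "philadelphia_prob": 0.37,
            "age_mean": 8.5,
            "age_sd": 4.6,
            "missing_index_insurance_prob": 0.0,
            "no_insurance_prob": 0.0,
        }
        for _ in range(k)
    ]


def recovery_vocabulary(n_items: int = 12) -> list[TemporalDiagnosis]:
    """``n_items`` synthetic codes split over timings 1 and 2."""
    half = n_items // 2
    return [TemporalDiagnosis(1, f"SYN{c:02d}") for c in range(half)] + [
        TemporalDiagnosis(2, f"SYN{c:02d}") for c in range(n_items - half)
    ]


def recovery_item_probs(k: int = 3, n_items: int = 12) -> np.ndarray:
    """Block-structured, well-separated ρ: each class owns a block of items at
    probability 0.8 against a 0.1 background."""
    rho = np.full((k, n_items), RECOVERY_LOW)
    block = n_items // k
    for c in range(k):
        rho[c, c * block : (c + 1) * block] = RECOVERY_HIGH
    return rho


def recovery_config(seed: int, n_cases: int = 5000, k: int = 3, n_items: int = 12) -> GeneratorConfig:
    return GeneratorConfig(
        n_cases=n_cases,
        k_true=k,
        mixing_weights=np.array(RECOVERY_MIXING[:k]) / sum(RECOVERY_MIXING[:k]),
        item_probs=recovery_item_probs(k, n_items),
        vocabulary=recovery_vocabulary(n_items),
        demographic_params=simple_demographics(k),
        seed=seed,
    )


def recovery_study(
    master_seed: int,
    n_replicates: int = 20,
    n_cases: int = 5000,
    k: int = 3,
    n_items: int = 12,
    k_min: int = 2,
    k_max: int = 5,
    n_starts: int = 4,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> dict:
    """Repeated parameter-recovery experiment.

    Each replicate draws a fresh cohort from :func:`recovery_config`, sweeps
    class counts ``k_min..k_max`` and records (a) which K the BIC selects and
    (b) the max-abs error of ρ̂ and π̂ for the true-K model after label
    matching. EM settings are deliberately economical: with well-separated
    classes the true-K fit converges in tens of iterations, and over-fitted
    class counts only drift along a near-flat likelihood ridge past
    ``max_iter``.

    Returns lists ``rho_errors``, ``pi_errors``, ``selected_k`` plus their
    summary statistics.
    """
    from .cohort_builder import build_temporal_features
    from .lca import derive_seed, sweep_models
    from .synthetic_cohort import generate_cases

    rho_errors, pi_errors, selected = [], [], []
    for rep in range(n_replicates):
        config = recovery_config(
            seed=derive_seed(master_seed, 100, rep), n_cases=n_cases, k=k, n_items=n_items
        )
        cases, _ = generate_cases(config)
        features = build_temporal_features(cases, config.vocabulary)
        sweep = sweep_models(
            features,
            k_min=k_min,
            k_max=k_max,
            n_starts=n_starts,
            max_iter=max_iter,
            tol=tol,
            seed=derive_seed(master_seed, 200, rep),
        )
        selected.append(sweep.selected_K)
        model = sweep.models[k]
        perm = list(match_permutation(config.item_probs, model.rho))
        rho_errors.append(float(np.abs(model.rho[perm] - config.item_probs).max()))
        pi_errors.append(float(np.abs(model.pi[perm] - config.mixing_weights).max()))
    return {
        "rho_errors": rho_errors,
        "pi_errors": pi_errors,
        "selected_k": selected,
        "median_rho_error": float(np.median(rho_errors)),
        "median_pi_error": float(np.median(pi_errors)),
        "true_k_selection_rate": float(np.mean([s == k for s in selected])),
    }


def mcnemar_null_calibration(
    seed: int,
    n_patterns: int = 1000,
    n_pairs: int = 2000,
    prevalence: float = 0.2,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the uncorrected McNemar test on null (odds ratio 1)
    patterns: case and control presence drawn independently at the same
    prevalence. Returns the rejection rate at ``alpha``."""
    from .pattern_stats import DiscordantCounts, mcnemar_test

    rng = np.random.default_rng(np.random.SeedSequence([seed, 300]))
    case = rng.random((n_patterns, n_pairs)) < prevalence
    ctrl = rng.random((n_patterns, n_pairs)) < prevalence
    b = (case & ~ctrl).sum(axis=1)
    c = (ctrl & ~case).sum(axis=1)
    rejections = sum(
        mcnemar_test(DiscordantCounts(int(bi), int(ci), n_pairs), correction=False)[1] < alpha
        for bi, ci in zip(b, c)
    )
    return rejections / n_patterns


def match_permutation(rho_true: np.ndarray, rho_fit: np.ndarray) -> tuple[int, ...]:
    """Permutation of fitted classes minimizing total |ρ̂ − ρ| (brute force;
    intended for small K)."""
    k = rho_true.shape[0]
    best, best_err = None, np.inf
    for perm in permutations(range(k)):
        err = np.abs(rho_fit[list(perm)] - rho_true).sum()
        if err < best_err:
            best, best_err = perm, err
    return best
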