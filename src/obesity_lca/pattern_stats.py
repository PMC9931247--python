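"""Matched case-control comparison of pattern prevalence via McNemar's test.

Each mined pattern is compared between cases and their 1:1 matched controls.
Only the discordant pairs carry information: b = pairs where the case has the
pattern and the control does not, c = the reverse. The asymptotic statistic is
(|b−c|−1)²/(b+c) with continuity correction (the default) or (b−c)²/(b+c)
without, referred to a chi-square distribution with 1 df. Patterns are
retained when significant *and* more prevalent among cases; an optional
Benjamini-Hochberg adjustment is available for false-discovery control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort_builder import FeatureMatrix
from .pattern_mining import SequencePattern, contains

DIRECTION_CASE = "case_enriched"
DIRECTION_CONTROL = "control_enriched"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class DiscordantCounts:
    """Discordant-pair counts for one pattern over the matched pairs."""

    b: int  # case has pattern, matched control does not
    c: int  # control has pattern, matched case does not
    n_pairs: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0 or self.n_pairs < 0:
            raise ValueError("counts must be non-negative")
        if self.b + self.c > self.n_pairs:
            raise ValueError("b + c cannot exceed n_pairs")


@dataclass
class PatternTestResult:
    pattern: SequencePattern
    case_prevalence: float
    control_prevalence: float
    b: int
    c: int
    n_pairs: int
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    significant: bool = False

    @property
    def direction(self) -> str:
        if self.case_prevalence > self.control_prevalence:
            return DIRECTION_CASE
        if self.control_prevalence > self.case_prevalence:
            return DIRECTION_CONTROL
        return DIRECTION_NONE


def discordant_counts(
    pattern: SequencePattern,
    case_sets: dict[str, frozenset],
    control_sets: dict[str, frozenset],
    match_pairs: dict[str, str],
) -> DiscordantCounts:
    """Per-pair presence comparison of one pattern.

    ``case_sets``/``control_sets`` map patient id → tagged feature set (see
    :meth:`obesity_lca.cohort_builder.FeatureMatrix.item_sets`).
    """
    b = c = 0
    for case_id, control_id in match_pairs.items():
        if case_id not in case_sets or control_id not in control_sets:
            raise ValueError(f"unmatched pair ({case_id!r}, {control_id!r})")
        in_case = contains(case_sets[case_id], pattern)
        in_control = contains(control_sets[control_id], pattern)
        b += in_case and not in_control
        c += in_control and not in_case
    return DiscordantCounts(b, c, len(match_pairs))


def mcnemar_test(counts: DiscordantCounts, correction: bool = True) -> tuple[float, float]:
    """Asymptotic McNemar statistic and two-sided chi-square(1) p-value.

    With no discordant pairs the statistic is 0 and p = 1.
    """
    b, c = counts.b, counts.c
    if b + c == 0:
        return 0.0, 1.0
    diff = abs(b - c) - 1 if correction else abs(b - c)
    diff = max(diff, 0)
    statistic = diff**2 / (b + c)
    return float(statistic), float(chi2.sf(statistic, df=1))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def compare_patterns(
    patterns: list[SequencePattern],
    case_features: FeatureMatrix,
    control_features: FeatureMatrix,
    match_pairs: dict[str, str],
    alpha: float = 0.05,
    adjust: str = "none",
    correction: bool = True,
) -> list[PatternTestResult]:
    """McNemar-test every pattern over the matched pairs and mark the
    significant, case-enriched ones.

    ``adjust`` is ``"none"`` (each raw p compared to alpha) or
    ``"benjamini_hochberg"``.
    """
    if adjust not in ("none", "benjamini_hochberg"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    case_sets = case_features.item_sets()
    control_sets = control_features.item_sets()
    n_pairs = len(match_pairs)
    results = []
    for pattern in patterns:
        counts = discordant_counts(pattern, case_sets, control_sets, match_pairs)
        stat, p = mcnemar_test(counts, correction)
        case_prev = sum(
            contains(case_sets[cid], pattern) for cid in match_pairs
        ) / n_pairs
        control_prev = sum(
            contains(control_sets[tid], pattern) for tid in match_pairs.values()
        ) / n_pairs
        results.append(
            PatternTestResult(
                pattern, case_prev, control_prev, counts.b, counts.c, n_pairs, stat, p
            )
        )
    p_adj = (
        benjamini_hochberg(np.array([r.p_value for r in results]))
        if adjust == "benjamini_hochberg" and results
        else [r.p_value for r in results]
    )
    for r, pa in zip(results, p_adj):
        r.p_adjusted = float(pa)
        r.significant = pa < alpha and r.direction == DIRECTION_CASE
    return results


def select_significant(results: list[PatternTestResult]) -> list[PatternTestResult]:
    """The significant, case-enriched subset (order preserved)."""
    return [r for r in results if r.significant]


def results_to_frame(results: list[PatternTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pattern": r.pattern.render(),
                "case_prev": r.case_prevalence,
                "control_prev": r.control_prevalence,
                "b": r.b,
                "c": r.c,
                "statistic": r.statistic,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
                "significant": int(r.significant),
            }
            for r in results
        ],
        columns=[
            "pattern",
            "case_prev",
            "control_prev",
            "b",
            "c",
            "statistic",
            "p",
            "p_adj",
            "significant",
        ],
    )


def write_results(results: list[PatternTestResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False, float_format="%.10g")
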