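"""Frequent temporal condition-pattern mining over the three study visits.

Patterns are ordered sets of timing-tagged diagnoses (timing 1 = pre-index,
2 = index, 3 = post-index), e.g. ``(1-ALL04, 2-EAR01)``. Because the timing
tags are absolute, "sequence containment" reduces to tagged-set inclusion:
a patient contains a pattern iff every tagged item appears in the patient's
feature set. Mining therefore runs as SPADE does — vertical id-lists per
pattern, level-wise Apriori candidate generation by prefix join, and support
counting by id-list intersection — with exact support fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort_builder import FeatureMatrix
from .temporal import TemporalDiagnosis, canonical_order


@dataclass(frozen=True)
class SequencePattern:
    """An ordered set of temporal diagnoses with its case support fraction.

    ``items`` is kept sorted in canonical (timing, code) order; support is the
    fraction of case patients whose tagged feature set contains every item.
    """

    items: tuple[TemporalDiagnosis, ...]
    support: float | None = None

    def __post_init__(self) -> None:
        if list(self.items) != canonical_order(self.items):
            raise ValueError("pattern items must be unique and in canonical order")
        if self.support is not None and not (0.0 <= self.support <= 1.0):
            raise ValueError("support must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.items)

    def render(self) -> str:
        return ",".join(t.render() for t in self.items)

    @classmethod
    def parse(cls, text: str, support: float | None = None) -> "SequencePattern":
        items = tuple(canonical_order(TemporalDiagnosis.parse(p) for p in text.split(",")))
        return cls(items, support)

    @property
    def sort_key(self):
        return (len(self.items), tuple(t.sort_key for t in self.items))


@dataclass
class MiningConfig:
    """``min_support`` is a fraction of case patients (default 1%);
    ``max_items`` caps pattern length (None = unlimited)."""

    min_support: float = 0.01
    max_items: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.min_support <= 1.0):
            raise ValueError(f"min_support must be in (0, 1], got {self.min_support}")


def contains(patient_features: frozenset[TemporalDiagnosis] | set, pattern: SequencePattern) -> bool:
    """True iff every item of the pattern is in the patient's tagged feature set.

    The empty pattern is vacuously contained in every patient.
    """
    return all(item in patient_features for item in pattern.items)


def mine_frequent_patterns(
    features: FeatureMatrix, config: MiningConfig | None = None
) -> list[SequencePattern]:
    """All patterns with support ≥ ``min_support`` among the given (case)
    patients, with exact supports.

    Level-wise growth: frequent single items seed vertical id-lists; candidate
    (k+1)-item patterns join two frequent k-item patterns sharing their first
    k−1 items, are pruned unless all k-item sub-patterns are frequent, and are
    counted by intersecting the parents' id-lists. Output is sorted by
    (length, then canonical item order).
    """
    config = config or MiningConfig()
    n = len(features.data)
    if n == 0:
        raise ValueError("feature matrix has no patients")
    min_count = config.min_support * n

    arr = features.data.to_numpy()
    vocab = features.vocabulary
    # vertical representation: item -> set of row indices
    id_lists: dict[tuple[TemporalDiagnosis, ...], frozenset[int]] = {}
    level: list[tuple[TemporalDiagnosis, ...]] = []
    for j, item in enumerate(vocab):
        ids = frozenset(arr[:, j].nonzero()[0].tolist())
        if len(ids) >= min_count:
            key = (item,)
            id_lists[key] = ids
            level.append(key)
    level.sort(key=lambda items: tuple(t.sort_key for t in items))

    results: list[SequencePattern] = [
        SequencePattern(items, len(id_lists[items]) / n) for items in level
    ]
    k = 1
    frequent_at_level = {1: set(level)}
    while level and (config.max_items is None or k < config.max_items):
        next_level: list[tuple[TemporalDiagnosis, ...]] = []
        for a in range(len(level)):
            for b in range(a + 1, len(level)):
                left, right = level[a], level[b]
                if left[:-1] != right[:-1]:
                    # level is sorted, so no later right shares this prefix
                    break
                candidate = left + (right[-1],)
                if not _all_subpatterns_frequent(candidate, frequent_at_level[k]):
                    continue
                ids = id_lists[left] & id_lists[right]
                if len(ids) >= min_count:
                    id_lists[candidate] = ids
                    next_level.append(candidate)
        next_level.sort(key=lambda items: tuple(t.sort_key for t in items))
        results.extend(
            SequencePattern(items, len(id_lists[items]) / n) for items in next_level
        )
        k += 1
        frequent_at_level[k] = set(next_level)
        level = next_level
    return results


def _all_subpatterns_frequent(candidate: tuple, frequent: set) -> bool:
    return all(
        candidate[:i] + candidate[i + 1 :] in frequent for i in range(len(candidate))
    )


def frequent_subsequences(patterns: list[SequencePattern]) -> list[TemporalDiagnosis]:
    """Deduplicated single items appearing in any pattern, in canonical order.

    These individual temporal diagnoses are the latent-class feature
    vocabulary: keeping a pattern *and* its sub-patterns as separate model
    indicators would violate conditional independence, since a pattern is the
    conjunction of its items.
    """
    return canonical_order(item for p in patterns for item in p.items)


def patterns_to_frame(patterns: list[SequencePattern], n_cases: int) -> pd.DataFrame:
    rows = [
        {
            "pattern": p.render(),
            "length": len(p),
            "support": p.support,
            "n_supporting": int(round(p.support * n_cases)),
        }
        for p in patterns
    ]
    return pd.DataFrame(rows, columns=["pattern", "length", "support", "n_supporting"])


def write_patterns(patterns: list[SequencePattern], n_cases: int, path: str | Path) -> None:
    patterns_to_frame(patterns, n_cases).to_csv(path, index=False, float_format="%.10g")


def read_patterns(path: str | Path) -> list[SequencePattern]:
    df = pd.read_csv(path, keep_default_na=False)
    return [SequencePattern.parse(r.pattern, float(r.support)) for r in df.itertuples()]
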