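"""Shared test utilities: feature-matrix builders and a brute-force miner."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from obesity_lca.cohort_builder import FeatureMatrix
from obesity_lca.pattern_mining import SequencePattern, contains
from obesity_lca.temporal import TemporalDiagnosis, canonical_order


def make_features(
    patient_items: dict[str, list[str]], vocabulary: list[str] | None = None
) -> FeatureMatrix:
    """Build a FeatureMatrix from {patient_id: ["1-A", "2-B", ...]}."""
    parsed = {
        pid: [TemporalDiagnosis.parse(t) for t in items]
        for pid, items in patient_items.items()
    }
    if vocabulary is None:
        vocab = canonical_order(t for items in parsed.values() for t in items)
    else:
        vocab = canonical_order(TemporalDiagnosis.parse(t) for t in vocabulary)
    col = {t: j for j, t in enumerate(vocab)}
    values = np.zeros((len(parsed), len(vocab)), dtype=np.uint8)
    for i, items in enumerate(parsed.values()):
        for t in items:
            values[i, col[t]] = 1
    data = pd.DataFrame(
        values,
        index=pd.Index(list(parsed), name="patient_id"),
        columns=[t.render() for t in vocab],
    )
    return FeatureMatrix(data, vocab)


def brute_force_mine(features: FeatureMatrix, min_support: float) -> dict[str, float]:
    """Exhaustively enumerate every tagged-itemset and count support by direct
    scan with ``contains``; independent oracle for the level-wise miner."""
    sets = list(features.item_sets().values())
    n = len(sets)
    vocab = features.vocabulary
    out: dict[str, float] = {}
    for size in range(1, len(vocab) + 1):
        for combo in combinations(vocab, size):
            pattern = SequencePattern(tuple(canonical_order(combo)))
            support = sum(contains(s, pattern) for s in sets) / n
            if support >= min_support:
                out[pattern.render()] = support
    return out


def random_toy_features(rng: np.random.Generator) -> FeatureMatrix:
    """A random small cohort (≤30 patients, ≤8 tagged items) for oracle trials."""
    n = int(rng.integers(5, 31))
    j = int(rng.integers(2, 9))
    vocab = [
        TemporalDiagnosis(int(rng.integers(1, 4)), f"C{i:02d}") for i in range(j)
    ]
    vocab = canonical_order(vocab)
    density = rng.uniform(0.1, 0.6)
    values = (rng.random((n, len(vocab))) < density).astype(np.uint8)
    data = pd.DataFrame(
        values,
        index=pd.Index([f"p{i}" for i in range(n)], name="patient_id"),
        columns=[t.render() for t in vocab],
    )
    return FeatureMatrix(data, vocab)
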