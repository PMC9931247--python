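"""Timing-tagged diagnosis codes: the atomic feature of the pipeline.

A *temporal diagnosis* is a diagnosis category code tagged with the study
visit at which it was recorded: 1 = pre-index (the visit immediately before
obesity incidence), 2 = index (the first visit with an obese BMI), 3 =
post-index (the visit immediately after). The rendered form is
``"<timing>-<code>"``, e.g. ``"1-ALL04"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering
from typing import Iterable

TIMING_PRE = 1
TIMING_INDEX = 2
TIMING_POST = 3
VALID_TIMINGS = (TIMING_PRE, TIMING_INDEX, TIMING_POST)

#: visit role labels used in the visits table ↔ timing integers
ROLE_TO_TIMING = {"pre": TIMING_PRE, "index": TIMING_INDEX, "post": TIMING_POST}
TIMING_TO_ROLE = {v: k for k, v in ROLE_TO_TIMING.items()}


@total_ordering
@dataclass(frozen=True)
class TemporalDiagnosis:
    """A diagnosis category code tagged with its visit timing class (1/2/3)."""

    timing: int
    code: str

    def __post_init__(self) -> None:
        if self.timing not in VALID_TIMINGS:
            raise ValueError(f"timing must be one of {VALID_TIMINGS}, got {self.timing!r}")
        if not self.code:
            raise ValueError("diagnosis code must be non-empty")

    def render(self) -> str:
        return f"{self.timing}-{self.code}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "TemporalDiagnosis":
        """Parse a rendered ``"t-code"`` string (code may itself contain dashes)."""
        timing_str, sep, code = text.partition("-")
        if not sep or not code:
            raise ValueError(f"not a temporal diagnosis: {text!r}")
        return cls(int(timing_str), code)

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.timing, self.code)

    def __lt__(self, other: "TemporalDiagnosis") -> bool:
        if not isinstance(other, TemporalDiagnosis):
            return NotImplemented
        return self.sort_key < other.sort_key


def canonical_order(items: Iterable[TemporalDiagnosis]) -> list[TemporalDiagnosis]:
    """Deduplicate and sort by (timing ascending, code lexicographic).

    This ordering is the canonical vocabulary order used everywhere a feature
    list is materialized, so outputs are byte-stable across runs.
    """
    return sorted(set(items))
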