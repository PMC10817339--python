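"""Adjusted ratio of clustering (ARC) for category-organized recall.

Given the ordered category labels of one test's recall output, ARC
compares the observed number of adjacent same-category repetitions R with
its permutation-null expectation E(R) = sum(n_i^2)/N - 1, normalized by
the attainable range so that 1 means perfect category clustering and 0
means chance-level clustering:

    ARC = (R - E(R)) / (maxR - E(R))   if R > E(R)
    ARC = (R - E(R)) / (E(R) - minR)   if R < E(R)
    ARC = 0                            if R = E(R)

with maxR = N - k and minR = 0 if N + 1 >= 2m else 2m - N - 1, where n_i
counts recalled items of category i, N is the total recalled, k the number
of categories represented and m the largest n_i.  ARC is undefined (not an
error) when N <= 1, only one category is recalled, or the applicable
denominator is zero; undefined values are excluded from condition means.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np

__all__ = [
    "RecallSequence",
    "CategoryComposition",
    "ARCResult",
    "count_repetitions",
    "expected_repetitions",
    "max_min_repetitions",
    "arc",
    "summarize_arc",
]

RecallSequence = Sequence[Hashable]  # ordered category labels of recalled items


@dataclass(frozen=True)
class CategoryComposition:
    """Category tallies (n_i, N, k, m) of one recall output."""

    per_category_counts: dict

    @classmethod
    def from_sequence(cls, seq: RecallSequence) -> "CategoryComposition":
        return cls(dict(Counter(seq)))

    @property
    def total_recalled(self) -> int:
        return sum(self.per_category_counts.values())

    @property
    def categories_recalled(self) -> int:
        return sum(1 for v in self.per_category_counts.values() if v > 0)

    @property
    def max_category_count(self) -> int:
        return max(self.per_category_counts.values(), default=0)


@dataclass(frozen=True)
class ARCResult:
    """Observed repetitions, chance expectation, range, and the ARC index.

    ``arc`` is ``None`` when the index is undefined for this output
    (single item, single category, or degenerate denominator).
    """

    repetitions: int
    expected_repetitions: float
    max_repetitions: int
    min_repetitions: int
    arc: Optional[float]

    @property
    def defined(self) -> bool:
        return self.arc is not None


def count_repetitions(seq: RecallSequence) -> int:
    """Number of adjacent positions occupied by the same category."""
    return sum(1 for a, b in zip(seq, seq[1:]) if a == b)


def expected_repetitions(comp: CategoryComposition) -> float:
    """Chance expectation E(R) = sum(n_i^2)/N - 1 under uniform ordering."""
    n = comp.total_recalled
    if n < 1:
        raise ValueError("E(R) is undefined for an empty recall output")
    return sum(v * v for v in comp.per_category_counts.values()) / n - 1.0


def max_min_repetitions(comp: CategoryComposition) -> tuple[int, int]:
    """Attainable repetition range: maxR = N - k; minR piecewise in m."""
    n = comp.total_recalled
    if n < 1:
        raise ValueError("repetition range is undefined for an empty output")
    k = comp.categories_recalled
    m = comp.max_category_count
    max_r = n - k
    min_r = 0 if n + 1 >= 2 * m else 2 * m - n - 1
    return max_r, min_r


def arc(seq: RecallSequence) -> ARCResult:
    """ARC index of one recall output's category clustering.

    The sequence holds the ordered category labels of the recalled
    study-list items (intrusions dropped, duplicates collapsed upstream).
    """
    comp = CategoryComposition.from_sequence(seq)
    n = comp.total_recalled
    if n == 0:
        return ARCResult(0, float("nan"), 0, 0, None)
    reps = count_repetitions(seq)
    e_r = expected_repetitions(comp)
    max_r, min_r = max_min_repetitions(comp)

    value: Optional[float]
    if n <= 1 or comp.categories_recalled == 1:
        value = None
    elif reps > e_r:
        denom = max_r - e_r
        value = (reps - e_r) / denom if denom > 0 else None
    elif reps < e_r:
        denom = e_r - min_r
        value = (reps - e_r) / denom if denom > 0 else None
    else:
        value = 0.0  # chance-level clustering by convention
    return ARCResult(reps, e_r, max_r, min_r, value)


def summarize_arc(results: Sequence[ARCResult]) -> dict:
    """Mean of the defined ARC values plus an exclusion tally."""
    defined = [r.arc for r in results if r.defined]
    return {
        "mean_arc": float(np.mean(defined)) if defined else float("nan"),
        "sd_arc": float(np.std(defined, ddof=1)) if len(defined) > 1 else float("nan"),
        "n_defined": len(defined),
        "n_undefined": len(results) - len(defined),
    }
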