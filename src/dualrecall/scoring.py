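"""Scoring of typed recall transcripts and participant-level screening.

Participants type recalled words in any order and are told not to worry
about spelling, so responses are normalized and matched to study words
with a small edit-distance tolerance before per-item correct/error flags
are derived.  Per-participant recall proportions feed the outlier rule:
within each design cell, a participant is excluded when their mean recall
exceeds the cell median by more than 1.5 interquartile ranges.  The rule
is deliberately upper-sided and anchored at the median (not Tukey fences);
a symmetric variant is available behind a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .model import PatternCounts

__all__ = [
    "RecallTranscript",
    "ScoredTest",
    "normalize_response",
    "score_recall",
    "build_patterns",
    "outlier_filter",
    "participant_summaries",
    "screen_outliers",
    "aggregate_patterns",
]


@dataclass(frozen=True)
class RecallTranscript:
    """One participant's ordered typed responses on one test."""

    participant_id: str
    test_index: int
    responses: tuple

    def __post_init__(self) -> None:
        if self.test_index not in (1, 2, 3):
            raise ValueError("test_index must be 1, 2 or 3")


@dataclass(frozen=True)
class ScoredTest:
    """Per-item recall flags and output positions for one scored test."""

    recalled: np.ndarray          # bool per study-list item
    output_positions: np.ndarray  # 1-based rank per item, 0 if unrecalled
    intrusions: tuple             # normalized responses matching no study word


def normalize_response(response: str) -> str:
    return re.sub(r"\s+", " ", response.strip().lower())


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def score_recall(
    transcript: RecallTranscript,
    study_words: Sequence[str],
    tolerance: int = 1,
) -> ScoredTest:
    """Match typed responses to study words, tolerating small misspellings.

    Responses are normalized (lowercased, trimmed, internal whitespace
    collapsed) and deduplicated (first occurrence kept).  Each response
    matches the first unmatched study word that equals it exactly, else
    the nearest unmatched word within ``tolerance`` edits (ties broken by
    study-list order).  Each study word is matched at most once; unmatched
    responses are recorded as intrusions.
    """
    if len(study_words) == 0:
        raise ValueError("study list must be non-empty")
    normalized_words = [normalize_response(w) for w in study_words]
    n = len(study_words)
    recalled = np.zeros(n, dtype=bool)
    positions = np.zeros(n, dtype=int)
    intrusions = []
    seen = set()
    rank = 0
    for raw in transcript.responses:
        resp = normalize_response(raw)
        if not resp or resp in seen:
            continue
        seen.add(resp)
        match = None
        for i, w in enumerate(normalized_words):
            if not recalled[i] and w == resp:
                match = i
                break
        if match is None and tolerance > 0:
            best = tolerance + 1
            for i, w in enumerate(normalized_words):
                if recalled[i]:
                    continue
                dist = _edit_distance(resp, w)
                if dist < best:
                    best, match = dist, i
            if best > tolerance:
                match = None
        if match is None:
            intrusions.append(resp)
        else:
            rank += 1
            recalled[match] = True
            positions[match] = rank
    return ScoredTest(recalled, positions, tuple(intrusions))


def build_patterns(
    flags_t1: Sequence, flags_t2: Sequence, flags_t3: Sequence
) -> tuple[np.ndarray, PatternCounts]:
    """Per-item canonical pattern indices plus this participant's tally."""
    f1, f2, f3 = (np.asarray(f, dtype=bool) for f in (flags_t1, flags_t2, flags_t3))
    if not (len(f1) == len(f2) == len(f3)):
        raise ValueError("recall flags must cover the same items on all 3 tests")
    idx = 4 * f1.astype(int) + 2 * f2.astype(int) + f3.astype(int)
    return idx, PatternCounts(np.bincount(idx, minlength=8))


def outlier_filter(
    values: Sequence[float], symmetric: bool = False
) -> tuple[np.ndarray, float]:
    """Included/excluded mask for one cell's mean-recall values.

    Excludes values more than 1.5 IQRs above the cell median (and, with
    ``symmetric=True``, equally far below).  Quartiles use linear
    interpolation.  With fewer than 4 values the filter is skipped.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        import warnings

        warnings.warn(
            "fewer than 4 participants in cell; outlier filter skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.ones(len(v), dtype=bool), float("nan")
    median = float(np.median(v))
    q1, q3 = np.percentile(v, [25, 75])
    iqr = float(q3 - q1)
    upper = median + 1.5 * iqr
    included = v <= upper
    if symmetric:
        included &= v >= median - 1.5 * iqr
    return included, upper


def participant_summaries(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant recall proportions on each test, with cell labels."""
    required = {
        "participant_id", "organization", "jol_condition",
        "recalled_t1", "recalled_t2", "recalled_t3",
    }
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    g = trial_table.groupby(
        ["participant_id", "organization", "jol_condition"], sort=True
    )
    out = g[["recalled_t1", "recalled_t2", "recalled_t3"]].mean().reset_index()
    out = out.rename(
        columns={f"recalled_t{t}": f"recall_proportion_t{t}" for t in (1, 2, 3)}
    )
    out["mean_recall"] = out[
        ["recall_proportion_t1", "recall_proportion_t2", "recall_proportion_t3"]
    ].mean(axis=1)
    return out


def screen_outliers(
    summaries: pd.DataFrame, symmetric: bool = False
) -> pd.DataFrame:
    """Apply the per-cell outlier rule to participant summaries.

    Adds an ``included`` flag; exclusions are decided within each
    (organization, jol_condition) cell on ``mean_recall``.
    """
    out = summaries.copy()
    out["included"] = True
    for _, idx in out.groupby(["organization", "jol_condition"]).groups.items():
        mask, _threshold = outlier_filter(
            out.loc[idx, "mean_recall"].to_numpy(), symmetric=symmetric
        )
        out.loc[idx, "included"] = mask
    return out


def aggregate_patterns(
    trial_table: pd.DataFrame, included_participants: Sequence | None = None
) -> dict:
    """Pool per-item patterns into per-cell ``PatternCounts``.

    Items are pooled within each (organization, jol_condition) cell across
    participants, one multinomial per cell.  ``included_participants``
    optionally restricts pooling to screened-in participants.
    """
    df = trial_table
    if included_participants is not None:
        df = df[df["participant_id"].isin(set(included_participants))]
    counts: dict = {}
    for (org, jol), cell in df.groupby(["organization", "jol_condition"]):
        _, pc = build_patterns(
            cell["recalled_t1"], cell["recalled_t2"], cell["recalled_t3"]
        )
        counts[(org, jol)] = pc
    return counts
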