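"""Planned behavioral comparisons and the full analysis report.

Implements the classical fixed-effects one-way ANOVA with partial
eta-squared, Fisher's LSD pairwise tests (unadjusted t tests on the
ANOVA's pooled error term), and the orchestration that takes a trial-level
table through outlier screening, recall ANOVAs, per-cell dual-retrieval
model fits, the Delta-G^2 comparison battery, and the test-1 ARC contrast
for randomized lists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arc import arc as _compute_arc
from .estimation import fit_all_conditions, fits_table
from .scoring import aggregate_patterns, participant_summaries, screen_outliers

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "one_way_anova",
    "pairwise_lsd",
    "arc_by_participant",
    "run_paper_analysis",
]


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way fixed-effects ANOVA summary."""

    f_statistic: float
    df_between: int
    df_within: int
    mse: float
    eta_p_squared: float
    p_value: float
    ss_between: float
    ss_within: float


@dataclass(frozen=True)
class PairwiseResult:
    """One LSD pairwise contrast on the ANOVA's pooled error term."""

    group_a: str
    group_b: str
    t_statistic: float
    df: int
    cohens_d: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA by sums of squares.

    ``MSE = SS_within / df_within`` and partial eta-squared is
    ``SS_between / (SS_between + SS_within)`` (identical to eta-squared in
    a one-way design).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("one_way_anova needs >= 2 groups with >= 2 observations each")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    if df_within < 1 or ss_within == 0:
        raise ValueError("degenerate groups: no within-group variance")
    msb = ss_between / df_between
    mse = ss_within / df_within
    f = msb / mse
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_between,
        df_within=df_within,
        mse=float(mse),
        eta_p_squared=float(ss_between / (ss_between + ss_within)),
        p_value=float(stats.f.sf(f, df_between, df_within)),
        ss_between=float(ss_between),
        ss_within=float(ss_within),
    )


def pairwise_lsd(
    groups: Mapping[str, Sequence[float]],
    pooled_mse: float,
    df_within: int,
) -> list[PairwiseResult]:
    """Fisher's LSD tests for every pair of groups.

    ``t = (M_a - M_b) / sqrt(MSE * (1/n_a + 1/n_b))`` with the ANOVA's
    within-cells df; ``Cohen's d = (M_a - M_b) / sqrt(MSE)``; p-values are
    deliberately unadjusted (the LSD convention).
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    results = []
    for a, b in itertools.combinations(names, 2):
        ga, gb = arrays[a], arrays[b]
        diff = ga.mean() - gb.mean()
        se = np.sqrt(pooled_mse * (1 / len(ga) + 1 / len(gb)))
        t = diff / se
        results.append(
            PairwiseResult(
                group_a=a,
                group_b=b,
                t_statistic=float(t),
                df=df_within,
                cohens_d=float(diff / np.sqrt(pooled_mse)),
                p_value=float(2 * stats.t.sf(abs(t), df_within)),
                mean_a=float(ga.mean()),
                sd_a=float(ga.std(ddof=1)),
                mean_b=float(gb.mean()),
                sd_b=float(gb.std(ddof=1)),
            )
        )
    return results


def arc_by_participant(trial_table: pd.DataFrame, test: int = 1) -> pd.DataFrame:
    """ARC of each participant's output order on the given test.

    The output order is reconstructed from the recorded output positions;
    the ARC of the resulting category sequence may be undefined (single
    category recalled, <= 1 item), in which case ``arc`` is NaN and
    ``defined`` False.
    """
    col = f"output_position_t{test}"
    rows = []
    for (pid, org, jol), part in trial_table.groupby(
        ["participant_id", "organization", "jol_condition"], sort=True
    ):
        recalled = part[part[col].notna()].sort_values(col)
        res = _compute_arc(list(recalled["category"]))
        rows.append(
            {
                "participant_id": pid,
                "organization": org,
                "jol_condition": jol,
                "test": test,
                "n_recalled": len(recalled),
                "repetitions": res.repetitions,
                "arc": res.arc if res.defined else np.nan,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)


def _one_tailed_t(ga: np.ndarray, gb: np.ndarray) -> dict:
    """Student's pooled-variance t of mean(a) > mean(b), one-tailed."""
    na, nb = len(ga), len(gb)
    df = na + nb - 2
    sp2 = (((ga - ga.mean()) ** 2).sum() + ((gb - gb.mean()) ** 2).sum()) / df
    t = (ga.mean() - gb.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return {
        "t_statistic": float(t),
        "df": df,
        "p_value": float(stats.t.sf(t, df)),
        "cohens_d": float((ga.mean() - gb.mean()) / np.sqrt(sp2)),
        "mean_a": float(ga.mean()),
        "sd_a": float(ga.std(ddof=1)),
        "mean_b": float(gb.mean()),
        "sd_b": float(gb.std(ddof=1)),
    }


REQUIRED_COLUMNS = (
    "participant_id", "organization", "jol_condition", "category",
    "recalled_t1", "recalled_t2", "recalled_t3",
)


def run_paper_analysis(
    trial_table: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    symmetric_outliers: bool = False,
) -> dict:
    """Full analysis of a trial-level table (synthetic or scored real data).

    Pipeline: per-cell outlier screening on mean recall -> test-1 recall
    one-way ANOVAs across JOL conditions within each list organization,
    with LSD pairwise contrasts -> per-cell dual-retrieval fits and the
    Delta-G^2 parameter-equality battery -> test-1 ARC contrast (item-JOL
    vs no-JOL, randomized lists, one-tailed pooled t).  Deterministic
    given the inputs and ``seed``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trial_table.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    if len(trial_table) == 0:
        raise ValueError("trial table is empty")

    summaries = screen_outliers(
        participant_summaries(trial_table), symmetric=symmetric_outliers
    )
    included = summaries.loc[summaries["included"], "participant_id"]
    excluded = summaries.loc[~summaries["included"], "participant_id"]

    # Test-1 recall ANOVAs across JOL conditions, one per organization.
    anovas: dict = {}
    lsd: dict = {}
    inc = summaries[summaries["included"]]
    for org, block in inc.groupby("organization"):
        groups = {
            jol: sub["recall_proportion_t1"].to_numpy()
            for jol, sub in block.groupby("jol_condition")
        }
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            res = one_way_anova(list(groups.values()))
            anovas[org] = res
            lsd[org] = pairwise_lsd(groups, res.mse, res.df_within)

    # Per-cell model fits and the parameter-equality battery.
    cell_counts = aggregate_patterns(trial_table, included)
    fits, comparisons = fit_all_conditions(
        cell_counts, n_starts=n_starts, seed=seed
    )

    # Test-1 ARC contrast for randomized lists: item-JOL vs no-JOL.
    arc_table = arc_by_participant(
        trial_table[trial_table["participant_id"].isin(set(included))], test=1
    )
    arc_summary = (
        arc_table[arc_table["defined"]]
        .groupby(["organization", "jol_condition"])["arc"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    arc_test = None
    rand = arc_table[
        (arc_table["organization"] == "randomized") & arc_table["defined"]
    ]
    ga = rand.loc[rand["jol_condition"] == "item", "arc"].to_numpy()
    gb = rand.loc[rand["jol_condition"] == "none", "arc"].to_numpy()
    if len(ga) >= 2 and len(gb) >= 2:
        arc_test = _one_tailed_t(ga, gb)

    return {
        "participant_summaries": summaries,
        "n_excluded": int(len(excluded)),
        "excluded_participants": list(excluded),
        "anova_test1": anovas,
        "lsd_test1": lsd,
        "model_fits": fits,
        "model_fits_table": fits_table(fits),
        "comparisons": comparisons,
        "arc_table": arc_table,
        "arc_summary": arc_summary,
        "arc_item_vs_none_randomized": arc_test,
        "seed": seed,
    }
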