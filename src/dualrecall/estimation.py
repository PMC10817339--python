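"""Maximum-likelihood fitting and likelihood-ratio testing.

A single condition's pattern counts are fit by maximizing the multinomial
log-likelihood over the six model parameters.  Goodness of fit is the
likelihood-ratio statistic

    G^2 = 2 * sum_i O_i * ln(O_i / (n * pi_i)),

which is asymptotically chi-square with 8 - 1 - 6 = 1 degree of freedom.
Cross-condition hypotheses (e.g., "J1 is equal in the item-JOL and no-JOL
conditions") are tested by Delta-G^2: the increase in G^2 when the named
parameter is equated across two conditions while all others stay free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    PARAM_NAMES,
    DualRetrievalParams,
    PatternCounts,
    PatternDistribution,
    _probabilities_from_vector,
    _probabilities_gradient,
)

__all__ = [
    "FitResult",
    "EqualityConstraint",
    "LRTestResult",
    "model_degrees_of_freedom",
    "critical_value",
    "g_squared",
    "fit",
    "lr_test",
    "fit_all_conditions",
]

_EPS = 1e-6          # box bounds keep the optimizer off the exact boundary
_LOG_FLOOR = 1e-12   # probability floor used only inside logarithms

#: Pairs of JOL conditions compared within each list organization,
#: mirroring the item-vs-no, list-vs-item, list-vs-no battery.
COMPARISON_PAIRS: tuple[tuple[str, str], ...] = (
    ("item", "none"),
    ("list", "item"),
    ("list", "none"),
)


def model_degrees_of_freedom(n_patterns: int = 8, n_params: int = 6) -> int:
    """Residual df: patterns minus the sum constraint minus free parameters."""
    return n_patterns - 1 - n_params


def critical_value(alpha: float = 0.05, df: int = 1) -> float:
    """Chi-square rejection threshold for the G^2 fit statistic."""
    return float(stats.chi2.ppf(1.0 - alpha, df))


@dataclass(frozen=True)
class FitResult:
    """A maximum-likelihood fit of one condition's pattern counts."""

    estimates: DualRetrievalParams
    g_squared: float
    df: int
    p_value: float
    log_likelihood: float
    converged: bool
    n_starts_used: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class EqualityConstraint:
    """Equate one model parameter across two conditions."""

    parameter_name: str
    condition_pair: tuple = ("a", "b")

    def __post_init__(self) -> None:
        if self.parameter_name not in PARAM_NAMES:
            raise ValueError(
                f"unknown parameter {self.parameter_name!r}; "
                f"expected one of {PARAM_NAMES}"
            )


@dataclass(frozen=True)
class LRTestResult:
    """Outcome of a Delta-G^2 parameter-equality test."""

    delta_g_squared: float
    df: int
    p_value: float
    free_fit_a: FitResult
    free_fit_b: FitResult
    constrained_fit_g_squared: float
    constrained_estimates_a: DualRetrievalParams = None
    constrained_estimates_b: DualRetrievalParams = None


def g_squared(observed: PatternCounts, expected_probs: PatternDistribution) -> float:
    """Likelihood-ratio goodness-of-fit statistic 2*sum O*ln(O/(n*pi)).

    Cells with ``O = 0`` contribute nothing (0*ln 0 := 0).  An expected
    probability of exactly zero under a non-empty cell makes the statistic
    infinite; it is returned as ``inf`` with a warning.
    """
    counts = observed.counts.astype(float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("g_squared requires at least one observed item")
    probs = expected_probs.probabilities
    nonzero = counts > 0
    if np.any(probs[nonzero] == 0.0):
        warnings.warn(
            "observed count in a cell with expected probability 0; "
            "G^2 is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    obs = counts[nonzero]
    exp = n * probs[nonzero]
    return float(max(2.0 * np.sum(obs * np.log(obs / exp)), 0.0))


def _saturated_loglik(counts: np.ndarray) -> float:
    c = counts[counts > 0].astype(float)
    n = c.sum()
    return float(np.sum(c * np.log(c / n)))


def _nll_and_grad(theta: np.ndarray, counts: np.ndarray):
    probs = _probabilities_from_vector(theta)
    safe = np.maximum(probs, _LOG_FLOOR)
    nll = -float(counts @ np.log(safe))
    grad = -(counts / safe) @ _probabilities_gradient(theta)
    return nll, grad


def _starts(n_starts: int, dim: int, seed: int, extra=None) -> list[np.ndarray]:
    pts = [np.full(dim, 0.5)]
    if extra is not None:
        pts.extend(np.clip(np.asarray(e, dtype=float), 0.02, 0.98) for e in extra)
    if n_starts > 0:
        sampler = stats.qmc.LatinHypercube(d=dim, seed=seed)
        pts.extend(0.02 + 0.96 * sampler.random(n_starts))
    return pts


def _optimize(objective, n_params: int, n_starts: int, seed: int, extra_starts=None):
    """Bounded quasi-Newton from stratified starts; returns the best optimum.

    Ties within 1e-9 of the best objective are broken by the
    lexicographically smaller parameter vector.
    """
    bounds = [(_EPS, 1.0 - _EPS)] * n_params
    best = None
    n_used = 0
    for x0 in _starts(n_starts, n_params, seed, extra_starts):
        n_used += 1
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None:
            best = res
        elif res.fun < best.fun - 1e-9:
            best = res
        elif abs(res.fun - best.fun) <= 1e-9 and tuple(res.x) < tuple(best.x):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    return best, n_used


def fit(
    observed: PatternCounts,
    n_starts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Fit the dual-retrieval model to one condition's pattern counts.

    Runs bounded L-BFGS-B from ``n_starts`` stratified (Latin hypercube)
    random starts plus a fixed midpoint start and keeps the best optimum.
    ``g_squared`` compares the fitted distribution with the saturated
    multinomial; the p-value comes from the chi-square(1) survival
    function.
    """
    counts = observed.counts.astype(float)
    n = counts.sum()
    if n < 1:
        raise ValueError("fit requires at least one observed item")

    res, n_used = _optimize(
        lambda th: _nll_and_grad(th, counts), 6, n_starts, seed
    )
    theta = np.asarray(res.x)
    ll = -float(res.fun)
    g2 = max(2.0 * (_saturated_loglik(counts) - ll), 0.0)
    df = model_degrees_of_freedom()
    warns = []
    if counts[0] == n:
        warns.append("degenerate data: all mass in EEE; boundary estimate")
    if np.any(theta <= _EPS * 1.01) or np.any(theta >= 1 - _EPS * 1.01):
        warns.append("estimate on parameter-space boundary")
    return FitResult(
        estimates=DualRetrievalParams.from_array(theta),
        g_squared=float(g2),
        df=df,
        p_value=float(stats.chi2.sf(g2, df)),
        log_likelihood=ll,
        converged=bool(res.success),
        n_starts_used=n_used,
        warnings=tuple(warns),
    )


def _joint_nll_and_grad(x: np.ndarray, counts_a, counts_b, shared_idx: int):
    """Constrained joint likelihood: 11 free values, one parameter shared."""
    theta_a = x[:6]
    theta_b = np.concatenate([x[6:6 + shared_idx], [x[shared_idx]], x[6 + shared_idx:]])
    nll_a, grad_a = _nll_and_grad(theta_a, counts_a)
    nll_b, grad_b = _nll_and_grad(theta_b, counts_b)
    grad = np.empty(11)
    grad[:6] = grad_a
    grad[shared_idx] += grad_b[shared_idx]
    grad[6:] = np.delete(grad_b, shared_idx)
    return nll_a + nll_b, grad


def lr_test(
    cond_a: PatternCounts,
    cond_b: PatternCounts,
    constraint: EqualityConstraint,
    n_starts: int = 20,
    seed: int = 0,
) -> LRTestResult:
    """Delta-G^2 test of one parameter's equality across two conditions.

    The constrained model shares the named parameter between the
    conditions and leaves the other five free in each; Delta-G^2 is the
    constrained joint G^2 minus the sum of the two free-fit G^2 values,
    referred to chi-square(1).  Small negative values (optimizer noise up
    to 1e-6) are floored at zero; anything more negative raises.
    """
    shared_idx = PARAM_NAMES.index(constraint.parameter_name)
    fit_a = fit(cond_a, n_starts=n_starts, seed=seed)
    fit_b = fit(cond_b, n_starts=n_starts, seed=seed + 1)

    counts_a = cond_a.counts.astype(float)
    counts_b = cond_b.counts.astype(float)

    # Warm start at the free optima, equated value = count-weighted average.
    ta, tb = fit_a.estimates.to_array(), fit_b.estimates.to_array()
    pooled = (ta[shared_idx] * counts_a.sum() + tb[shared_idx] * counts_b.sum()) / (
        counts_a.sum() + counts_b.sum()
    )
    warm = np.empty(11)
    warm[:6] = ta
    warm[shared_idx] = pooled
    warm[6:] = np.delete(tb, shared_idx)

    res, _ = _optimize(
        lambda x: _joint_nll_and_grad(x, counts_a, counts_b, shared_idx),
        11,
        n_starts,
        seed + 2,
        extra_starts=[warm],
    )
    ll_joint = -float(res.fun)
    sat = _saturated_loglik(counts_a) + _saturated_loglik(counts_b)
    g2_joint = max(2.0 * (sat - ll_joint), 0.0)
    delta = g2_joint - (fit_a.g_squared + fit_b.g_squared)
    if delta < -1e-6:
        raise RuntimeError(
            f"constrained joint fit did not converge: Delta-G^2 = {delta:.3g} < 0"
        )
    delta = max(delta, 0.0)

    x = np.asarray(res.x)
    est_a = DualRetrievalParams.from_array(x[:6])
    theta_b = np.concatenate(
        [x[6:6 + shared_idx], [x[shared_idx]], x[6 + shared_idx:]]
    )
    est_b = DualRetrievalParams.from_array(theta_b)
    return LRTestResult(
        delta_g_squared=float(delta),
        df=1,
        p_value=float(stats.chi2.sf(delta, 1)),
        free_fit_a=fit_a,
        free_fit_b=fit_b,
        constrained_fit_g_squared=float(g2_joint),
        constrained_estimates_a=est_a,
        constrained_estimates_b=est_b,
    )


def fit_all_conditions(
    dataset: Mapping,
    n_starts: int = 20,
    seed: int = 0,
    holm: bool = False,
):
    """Fit every condition and run the pairwise parameter-equality battery.

    ``dataset`` maps condition keys to :class:`PatternCounts`.  Keys of the
    form ``(organization, jol_condition)`` with JOL labels in
    ``{"item", "list", "none"}`` trigger the within-organization battery
    (item vs none, list vs item, list vs none) for all six parameters;
    other key shapes yield fits with an empty comparison table.

    Returns ``(fits, comparisons)`` where ``fits`` maps each key to its
    :class:`FitResult` and ``comparisons`` is a DataFrame with one row per
    (organization, parameter, pair) test.  ``holm`` adds Holm-adjusted
    p-values; raw p-values are always reported.
    """
    if len(dataset) == 0:
        raise ValueError("fit_all_conditions requires at least one condition")
    fits = {
        key: fit(counts, n_starts=n_starts, seed=seed + i)
        for i, (key, counts) in enumerate(sorted(dataset.items(), key=lambda kv: str(kv[0])))
    }

    rows = []
    structured = all(
        isinstance(k, tuple) and len(k) == 2 for k in dataset
    )
    if structured:
        organizations = sorted({k[0] for k in dataset})
        for org in organizations:
            for jol_a, jol_b in COMPARISON_PAIRS:
                ka, kb = (org, jol_a), (org, jol_b)
                if ka not in dataset or kb not in dataset:
                    continue
                for pname in PARAM_NAMES:
                    test = lr_test(
                        dataset[ka],
                        dataset[kb],
                        EqualityConstraint(pname, (ka, kb)),
                        n_starts=n_starts,
                        seed=seed,
                    )
                    rows.append(
                        {
                            "organization": org,
                            "parameter": pname,
                            "condition_a": jol_a,
                            "condition_b": jol_b,
                            "estimate_a": getattr(
                                test.free_fit_a.estimates,
                                _param_field(pname),
                            ),
                            "estimate_b": getattr(
                                test.free_fit_b.estimates,
                                _param_field(pname),
                            ),
                            "delta_g_squared": test.delta_g_squared,
                            "df": test.df,
                            "p_value": test.p_value,
                        }
                    )
    comparisons = pd.DataFrame(
        rows,
        columns=[
            "organization", "parameter", "condition_a", "condition_b",
            "estimate_a", "estimate_b", "delta_g_squared", "df", "p_value",
        ],
    )
    if holm and len(comparisons):
        comparisons["p_holm"] = _holm(comparisons["p_value"].to_numpy())
    return fits, comparisons


def _param_field(name: str) -> str:
    from .model import _FIELD_BY_NAME

    return _FIELD_BY_NAME[name]


def _holm(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def fits_table(fits: Mapping) -> pd.DataFrame:
    """Per-condition parameter grid (condition, G^2, D, F, J1, J2, J3, R)."""
    rows = []
    for key, fr in fits.items():
        d, f, j1, j2, j3, r = fr.estimates.to_array()
        row = {"condition": key, "G2": fr.g_squared,
               "D": d, "F": f, "J1": j1, "J2": j2, "J3": j3, "R": r}
        rows.append(row)
    return pd.DataFrame(rows)
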