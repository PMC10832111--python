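"""Signature scoring and minimum-p log-rank cut-off scanning on bulk cohorts.

A cohort is a sample x gene expression matrix (standardized per gene within
the cohort) with right-censored overall survival. Samples are scored by the
mean standardized expression of a refined marker gene set; the score
cut-point that best separates survival is found by scanning a fixed-step
grid between the first and third score quartiles and taking the cut-off
with the smallest log-rank p-value. Because the minimum is taken over many
tests, the optimal p is optimistic; cut-offs are therefore validated by
transferring them to an independent cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .markers import score_gene_set

__all__ = [
    "CohortTable",
    "CutoffScan",
    "KMEstimate",
    "standardize_expression",
    "subcluster_score",
    "logrank_test",
    "scan_cutoff",
    "cross_validate_cutoff",
    "km_estimate",
]


def standardize_expression(expr: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score every gene column within the cohort; constant genes are dropped."""
    sd = expr.std(ddof=ddof)
    keep = sd > 0
    return (expr.loc[:, keep] - expr.loc[:, keep].mean()) / sd[keep]


@dataclass
class CohortTable:
    """Standardized sample x gene expression with right-censored survival."""

    expr: pd.DataFrame
    os_time: pd.Series
    os_event: pd.Series

    @classmethod
    def from_raw(
        cls, expr: pd.DataFrame, os_time: pd.Series, os_event: pd.Series
    ) -> "CohortTable":
        expr = expr.loc[os_time.index]
        return cls(
            expr=standardize_expression(expr),
            os_time=os_time.astype(float),
            os_event=os_event.astype(int),
        )

    def validate(self, tol: float = 1e-8) -> None:
        if not (self.os_time > 0).all():
            raise ValueError("survival times must be positive")
        if not self.os_event.isin([0, 1]).all():
            raise ValueError("event indicators must be 0/1")
        means = self.expr.mean().abs()
        sds = (self.expr.std(ddof=1) - 1.0).abs()
        if (means > tol).any() or (sds > tol).any():
            raise ValueError("expression is not standardized (per-gene mean 0, sd 1)")


def subcluster_score(cohort: CohortTable, refined_set) -> pd.Series:
    """Per-sample mean standardized expression over a refined marker set."""
    return score_gene_set(cohort.expr, refined_set)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value)."""
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    events_a = np.asarray(events_a, int)
    events_b = np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if (times_a <= 0).any() or (times_b <= 0).any():
        raise ValueError("survival times must be positive")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("no events in either group; log-rank test is degenerate")
        return 0.0, 1.0
    res = _lifelines_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CutoffScan:
    """Result of a minimum-p log-rank cut-off scan over the Q1-Q3 grid."""

    q1: float
    q3: float
    step: float
    candidates: np.ndarray  # evaluated candidates
    pvalues: np.ndarray
    skipped: np.ndarray  # candidates dropped by the minimum group-size guard
    optimal_cutoff: float
    optimal_p: float


def scan_cutoff(
    scores,
    os_time,
    os_event,
    step: float = 0.04,
    min_group: int = 5,
) -> CutoffScan:
    """Scan candidate cut-offs between Q1 and Q3 for the minimum log-rank p.

    Candidates run from the first quartile upward in increments of ``step``
    without exceeding the third quartile (linear-interpolation quantiles).
    At each candidate ``c`` samples split into score > c versus score <= c;
    candidates leaving either group below ``min_group`` are skipped. Ties in
    the minimum p-value break toward the candidate nearest the score median.
    """
    scores = np.asarray(scores, float)
    os_time = np.asarray(os_time, float)
    os_event = np.asarray(os_event, int)
    if scores.size < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} samples")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    n_cand = int(np.floor((q3 - q1) / step + 1e-9)) + 1
    grid = q1 + step * np.arange(n_cand)

    cands, pvals, skipped = [], [], []
    for c in grid:
        high = scores > c
        if high.sum() < min_group or (~high).sum() < min_group:
            skipped.append(c)
            continue
        _, p = logrank_test(os_time[high], os_event[high], os_time[~high], os_event[~high])
        cands.append(c)
        pvals.append(p)
    if not cands:
        raise ValueError("every candidate cut-off was skipped by the group-size guard")
    cands = np.asarray(cands)
    pvals = np.asarray(pvals)
    best_p = pvals.min()
    tied = np.nonzero(pvals == best_p)[0]
    median = np.median(scores)
    best = tied[np.argmin(np.abs(cands[tied] - median))]
    return CutoffScan(
        q1=float(q1),
        q3=float(q3),
        step=step,
        candidates=cands,
        pvalues=pvals,
        skipped=np.asarray(skipped),
        optimal_cutoff=float(cands[best]),
        optimal_p=float(best_p),
    )


def cross_validate_cutoff(
    train: CohortTable,
    test: CohortTable,
    refined_set,
    step: float = 0.04,
    min_group: int = 5,
) -> dict:
    """Train a cut-off on one cohort, apply it unchanged to another.

    Both cohorts are scored by the same refined marker set on their own
    standardized expression; the optimal cut-off from the training scan
    splits the test cohort, and log-rank p-values for both splits are
    reported. An empty test group yields ``p_test = NaN`` with a warning.
    """
    train_scores = subcluster_score(train, refined_set)
    scan = scan_cutoff(train_scores, train.os_time, train.os_event, step, min_group)
    test_scores = subcluster_score(test, refined_set).to_numpy()
    high = test_scores > scan.optimal_cutoff
    if high.sum() == 0 or (~high).sum() == 0:
        warnings.warn("transferred cut-off leaves an empty test group; p_test is NaN")
        p_test = float("nan")
    else:
        t = test.os_time.to_numpy()
        e = test.os_event.to_numpy()
        _, p_test = logrank_test(t[high], e[high], t[~high], e[~high])
    return {"cutoff": scan.optimal_cutoff, "p_train": scan.optimal_p, "p_test": p_test, "scan": scan}


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray


def km_estimate(times, events) -> KMEstimate:
    """Product-limit survival estimate with right censoring; S(0) = 1."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMEstimate(times=sf.index.to_numpy(float), survival=sf.iloc[:, 0].to_numpy(float))
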