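"""Two-miRNA patient stratification and survival comparison.

Patients are split into two groups by 2-means clustering on the expression
of an interacting miRNA pair (each miRNA standardized first, since the two
measurements need not share a scale), then the groups' survival is compared
with the Kaplan-Meier product-limit estimator and the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate: step times and probabilities."""

    times: np.ndarray  # distinct observed times, ascending
    survival: np.ndarray  # S(t) just after each time; starts from S(0)=1

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if ((s < 0) | (s > 1)).any() or (np.diff(s) > 1e-12).any():
            raise ValueError("survival probabilities must be non-increasing in [0, 1]")


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 degree of freedom
    pvalue: float
    df: int = 1


def cluster_two_mirnas(
    patients: pd.DataFrame, seed: int = 0, standardize: bool = True
) -> np.ndarray:
    """2-means group labels (1 or 2) from the (expr_a, expr_b) plane.

    Runs 25 seeded restarts and keeps the lowest within-cluster sum of
    squares.  Group 1 is the cluster with the higher mean expr_a (so with
    miR-31 as miRNA A, group 1 is the high-miR-31 group).
    """
    if len(patients) < 2:
        raise ValueError("clustering needs at least 2 patients")
    points = patients[["expr_a", "expr_b"]].to_numpy(dtype=float)
    if np.allclose(points, points[0]):
        raise ValueError("all patients identical: no meaningful 2-means split")
    if standardize:
        std = points.std(axis=0, ddof=0)
        std[std == 0] = 1.0
        points = (points - points.mean(axis=0)) / std
    km = KMeans(n_clusters=2, n_init=25, random_state=seed)
    raw = km.fit_predict(points)
    mean_a = [points[raw == c, 0].mean() for c in (0, 1)]
    high_a = int(np.argmax(mean_a))
    return np.where(raw == high_a, 1, 2)


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    sf = fitter.survival_function_["KM_estimate"]
    return KMCurve(
        times=sf.index.to_numpy(dtype=float), survival=sf.to_numpy(dtype=float)
    )


def logrank(times, events, groups) -> LogRankResult:
    """Two-group log-rank test.

    Standard observed-minus-expected chi-square with the hypergeometric
    variance of the event count at each distinct event time (all deaths at a
    tied time enter one risk-set evaluation); p from chi-square with 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if not (len(times) == len(events) == len(groups)):
        raise ValueError("times, events and groups must have equal length")
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    mask = groups == labels[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("each group must contain at least one patient")
    result = _lifelines_logrank(
        times[mask], times[~mask], event_observed_A=events[mask],
        event_observed_B=events[~mask],
    )
    return LogRankResult(
        statistic=float(result.test_statistic), pvalue=float(result.p_value)
    )


def compare_groups(patients: pd.DataFrame, labels: np.ndarray) -> dict:
    """KM curves per group plus the log-rank comparison, as one result dict."""
    curves = {}
    for label in np.unique(labels):
        sel = labels == label
        curves[int(label)] = km_curve(
            patients.loc[sel, "time"], patients.loc[sel, "event"]
        )
    test = logrank(patients["time"], patients["event"], labels)
    sizes = {int(l): int((labels == l).sum()) for l in np.unique(labels)}
    return {"curves": curves, "logrank": test, "group_sizes": sizes}


def exhaustive_two_means_1d(values) -> np.ndarray:
    """Brute-force optimal 2-partition of 1-D points by within-cluster SS.

    Test oracle for :func:`cluster_two_mirnas` on one-dimensional data; the
    optimal 2-means partition in 1-D is a threshold split, but this searches
    every 2-partition outright.  Labels: 1 for the higher-mean cluster.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    best, best_ss = None, np.inf
    indices = range(n)
    for size in range(1, n // 2 + 1):
        for subset in combinations(indices, size):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            ss = 0.0
            for part in (values[mask], values[~mask]):
                ss += float(((part - part.mean()) ** 2).sum())
            if ss < best_ss - 1e-12:
                best_ss, best = ss, mask.copy()
    high = values[best].mean() >= values[~best].mean()
    return np.where(best, 1 if high else 2, 2 if high else 1)
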