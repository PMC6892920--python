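"""Panel evaluation: clustering, projection and survival analysis.

Expression matrices are transcripts x samples; samples are the clustering
units.  Survival uses the product-limit (Kaplan-Meier) estimator and the
multi-group log-rank chi-square test; both are implemented directly so that
they are deterministic and cheap enough for calibration simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "row_center",
    "ClusterAssignment",
    "hierarchical_cluster",
    "pca_project",
    "kmeans_cluster",
    "SurvivalCurve",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "dichotomize_by_median",
]


def row_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each transcript row's mean (idempotent)."""
    return matrix.sub(matrix.mean(axis=1), axis=0)


@dataclass
class ClusterAssignment:
    labels: pd.Series
    method: str
    k: int

    def composition(self, truth: pd.Series) -> pd.DataFrame:
        """Cluster x true-label contingency table."""
        return pd.crosstab(self.labels, truth.loc[self.labels.index])


def hierarchical_cluster(
    matrix: pd.DataFrame,
    k: int,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[ClusterAssignment, np.ndarray]:
    """Agglomerative clustering of samples on row-centered data.

    Returns the assignment at ``k`` clusters and the scipy merge tree.
    scipy's linkage resolves ties by merging the lower-index pair first,
    so the result is deterministic.
    """
    centered = row_center(matrix)
    tree = linkage(centered.to_numpy().T, method=method, metric=metric)
    labels = fcluster(tree, t=k, criterion="maxclust")
    return (
        ClusterAssignment(pd.Series(labels, index=matrix.columns), "hierarchical", k),
        tree,
    )


def pca_project(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto the top principal components of the
    feature-centered data.

    Component sign is fixed by making the largest-magnitude loading
    positive, so projections are reproducible across runs/backends.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x features
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for j in range(scores.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{j + 1}" for j in range(scores.shape[1])],
    )


def kmeans_cluster(
    matrix: pd.DataFrame, k: int = 5, restarts: int = 50, seed: int = 0
) -> ClusterAssignment:
    """k-means over samples: k-means++ starts, best of ``restarts`` runs by
    within-cluster sum of squares, deterministic given ``seed``."""
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(matrix.to_numpy(dtype=float).T)
    return ClusterAssignment(pd.Series(labels, index=matrix.columns), "kmeans", k)


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) evaluated at the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Censored observations (event = 0) leave the risk set without
    contributing an event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    n = times.size
    n_at_risk = np.empty(event_times.size)
    n_events = np.empty(event_times.size)
    surv = np.empty(event_times.size)
    s = 1.0
    for i, t in enumerate(event_times):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        n_at_risk[i], n_events[i], surv[i] = at_risk, d, s
    return SurvivalCurve(event_times, n_at_risk, n_events, surv)


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


def logrank_test(groups) -> LogrankResult:
    """Multi-group log-rank test.

    ``groups`` is a sequence of ``(times, events)`` pairs.  The statistic is
    the observed-minus-expected chi-square over the pooled distinct event
    times, using the hypergeometric variance-covariance of the per-time
    event allocation, on g-1 degrees of freedom.
    """
    g = len(groups)
    if g < 2:
        raise ValueError("log-rank needs >= 2 groups")
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=int) for _, e in groups]
    pooled = np.unique(np.concatenate([t[e == 1] for t, e in zip(times, events)]))
    observed = np.zeros(g)
    expected = np.zeros(g)
    cov = np.zeros((g, g))
    for t in pooled:
        n_i = np.array([(ti >= t).sum() for ti in times], dtype=float)
        d_i = np.array(
            [((ti == t) & (ei == 1)).sum() for ti, ei in zip(times, events)],
            dtype=float,
        )
        n_tot = n_i.sum()
        d_tot = d_i.sum()
        if n_tot < 2 or d_tot == 0:
            continue
        observed += d_i
        expected += d_tot * n_i / n_tot
        hyper = d_tot * (n_tot - d_tot) / (n_tot - 1.0)
        p_i = n_i / n_tot
        cov += hyper * (np.diag(p_i) - np.outer(p_i, p_i))
    diff = (observed - expected)[:-1]
    vmat = cov[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(vmat) @ diff) if diff.size else 0.0
    stat = max(stat, 0.0)
    df = g - 1
    return LogrankResult(stat, df, float(stats.chi2.sf(stat, df)))


def dichotomize_by_median(values) -> np.ndarray:
    """'high'/'low' labels by the study-specific median; values at the
    median count as high."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    return np.where(values >= med, "high", "low")
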