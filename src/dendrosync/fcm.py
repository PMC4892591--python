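"""Fuzzy C-means partitioning of site responses in fixed climate intervals.

Site chronologies are cut to short fixed windows (e.g. the 16 cold winters
1965–1980 and the 16 warm winters 1990–2005), each site's row z-scored, and
partitioned with fuzzy C-means: soft memberships u_ij in [0,1] summing to 1
per site, minimizing ``J = ΣΣ u_ij^m ||x_i - c_j||²`` by alternating
optimization. Partitions are summarized by fuzzy cardinalities, the
between-centroid distance, a fuzzy pseudo-F (Calinski–Harabasz form), and
the number of interval years with a significant between-cluster difference
(Welch t-test at α = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FuzzyCMeans",
    "FCMResult",
    "extract_interval_matrix",
    "zscore_rows",
    "fcm",
    "pseudo_f",
    "cluster_contrast_years",
    "partition_summary",
]


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy C-means clustering (alternating optimization, seeded restarts).

    Parameters
    ----------
    n_clusters : int, default 2
    m : float, default 2.0
        Fuzzifier (> 1). As m -> 1+ hard assignments converge to k-means.
    tol : float, default 1e-5
        Convergence threshold on the max membership change.
    max_iter : int, default 300
    n_init : int, default 10
        Seeded restarts; the run with the lowest final objective is kept.
    random_state : int or None

    Attributes (after fit)
    ----------------------
    membership_ : (n_samples, n_clusters), rows sum to 1
    cluster_centers_ : (n_clusters, n_features)
    labels_ : argmax membership
    objective_ : final J of the best restart
    objective_history_ : J per iteration of the best restart (non-increasing)
    n_iter_ : iterations of the best restart
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0, tol: float = 1e-5,
                 max_iter: int = 300, n_init: int = 10, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def _memberships(self, d2: np.ndarray) -> np.ndarray:
        # u_ij = 1 / sum_l (d_ij/d_il)^(2/(m-1)); log-space for small m-1
        expo = 1.0 / (self.m - 1.0)
        zero = d2 <= 1e-30
        logd = np.where(zero, 0.0, np.log(np.maximum(d2, 1e-300)))
        logw = -expo * logd
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        u = w / w.sum(axis=1, keepdims=True)
        # a sample exactly on a centroid gets full membership there
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        p, _ = X.shape
        k = self.n_clusters
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        if p <= k:
            raise ValueError(f"need more samples ({p}) than clusters ({k})")
        if np.allclose(X, X[0]):
            raise ValueError("degenerate input: all rows identical")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            u = rng.dirichlet(np.ones(k), size=p)
            history: list[float] = []
            for it in range(self.max_iter):
                um = u ** self.m
                centers = (um.T @ X) / um.sum(axis=0)[:, None]
                d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
                j = float(np.sum(um * d2))
                history.append(j)
                u_new = self._memberships(d2)
                if np.max(np.abs(u_new - u)) < self.tol:
                    u = u_new
                    break
                u = u_new
            um = u ** self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
            j = float(np.sum(um * d2))
            history.append(j)
            if best is None or j < best[0]:
                best = (j, u, centers, history, it + 1)
        j, u, centers, history, n_iter = best
        order = np.argsort(-u.sum(axis=0))   # descending fuzzy cardinality
        self.membership_ = u[:, order]
        self.cluster_centers_ = centers[order]
        self.labels_ = np.argmax(self.membership_, axis=1)
        self.objective_ = j
        self.objective_history_ = np.array(history)
        self.n_iter_ = n_iter
        self.X_fit_ = X
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=-1)
        return np.argmax(self._memberships(d2), axis=1)


@dataclass
class FCMResult:
    """Fitted FCM partition of an interval matrix plus its summaries."""

    memberships: pd.DataFrame        # site x cluster
    centroids: np.ndarray
    cardinalities: np.ndarray        # fuzzy cardinality per cluster
    centroid_distance: float
    objective: float
    objective_history: np.ndarray
    m: float
    seed: int | None
    restarts: int
    iterations: int
    data: pd.DataFrame               # the matrix as clustered (after row z-scoring)
    pseudo_f: float | None = None
    pseudo_f_infinite: bool = False
    n_significant_years: int | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.memberships.to_numpy(), axis=1)

    @property
    def sites(self) -> list[str]:
        return list(self.memberships.index)


def extract_interval_matrix(chronologies: pd.DataFrame, years: tuple[int, int]) -> pd.DataFrame:
    """Site × year matrix of raw index values for an inclusive year range."""
    span = np.arange(years[0], years[1] + 1)
    missing = [c for c in chronologies.columns
               if chronologies[c].reindex(span).isna().any()]
    if missing:
        raise ValueError(f"sites {missing} do not cover {years[0]}-{years[1]}")
    return chronologies.reindex(span).T.copy()


def zscore_rows(X: pd.DataFrame) -> pd.DataFrame:
    """Z-score each site row (mean 0, SD 1); raises if a row is constant."""
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = list(X.index[sd == 0])
        raise ValueError(f"constant rows cannot be z-scored: {bad}")
    return pd.DataFrame((arr - arr.mean(axis=1, keepdims=True)) / sd[:, None],
                        index=X.index, columns=X.columns)


def fcm(X: pd.DataFrame, k: int = 2, m: float = 2.0, tol: float = 1e-5,
        max_iter: int = 300, restarts: int = 10, seed: int | None = None,
        standardize_rows: bool = True) -> FCMResult:
    """Cluster an interval matrix; returns the full :class:`FCMResult`.

    Rows are z-scored first unless ``standardize_rows`` is False. Clusters
    are reported in descending fuzzy-cardinality order. The pseudo-F is
    always computed; the between-cluster year count only when both hard
    groups have at least two members.
    """
    Xz = zscore_rows(X) if standardize_rows else X.copy()
    est = FuzzyCMeans(n_clusters=k, m=m, tol=tol, max_iter=max_iter,
                      n_init=restarts, random_state=seed).fit(Xz.to_numpy())
    card = est.membership_.sum(axis=0)
    dist = float(np.linalg.norm(est.cluster_centers_[0] - est.cluster_centers_[1])) \
        if k == 2 else float("nan")
    res = FCMResult(
        memberships=pd.DataFrame(est.membership_, index=Xz.index,
                                 columns=[f"cluster{j+1}" for j in range(k)]),
        centroids=est.cluster_centers_,
        cardinalities=card,
        centroid_distance=dist,
        objective=est.objective_,
        objective_history=est.objective_history_,
        m=m, seed=seed, restarts=restarts, iterations=est.n_iter_,
        data=Xz,
    )
    pf, inf = pseudo_f(Xz, res, return_flag=True)
    res.pseudo_f, res.pseudo_f_infinite = pf, inf
    labels = res.labels
    if all(np.sum(labels == j) >= 2 for j in range(k)):
        res.n_significant_years = cluster_contrast_years(Xz, res)
    return res


def pseudo_f(X: pd.DataFrame, result: FCMResult, return_flag: bool = False):
    """Fuzzy pseudo-F: between-cluster over within-cluster dispersion,
    membership-weighted (Calinski–Harabasz form)."""
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    u = result.memberships.to_numpy()
    um = u ** result.m
    c = result.centroids
    p, k = u.shape
    grand = arr.mean(axis=0)
    between = float(np.sum(um * np.sum((c[None, :, :] - grand) ** 2, axis=-1)))
    within = float(np.sum(um * np.sum((arr[:, None, :] - c[None, :, :]) ** 2, axis=-1)))
    if within <= 1e-30:
        val = float("inf")
        return (val, True) if return_flag else val
    val = (between / (k - 1)) / (within / (p - k))
    return (val, False) if return_flag else val


def cluster_contrast_years(X: pd.DataFrame, result: FCMResult, alpha: float = 0.05) -> int:
    """Count of interval years whose values differ between the two hard
    groups (Welch t-test, two-sided, p < alpha)."""
    labels = result.labels
    arr = X.to_numpy(dtype=float)
    g0, g1 = arr[labels == 0], arr[labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both clusters need >= 2 members for the year-wise test")
    _, p = scipy.stats.ttest_ind(g0, g1, axis=0, equal_var=False)
    return int(np.sum(p < alpha))


def partition_summary(cold: FCMResult, warm: FCMResult) -> pd.DataFrame:
    """Side-by-side record of the two interval partitions and their
    warm-minus-cold differences."""
    if cold.sites != warm.sites:
        raise ValueError("interval partitions cover different site sets")

    def row(r: FCMResult) -> dict:
        return {
            "cluster_distance": r.centroid_distance,
            "group1": float(r.cardinalities[0]),
            "group2": float(r.cardinalities[1]),
            "pseudo_f": r.pseudo_f,
            "n_significant_years": r.n_significant_years,
        }

    cold_row, warm_row = row(cold), row(warm)
    diff = {key: (warm_row[key] - cold_row[key]
                  if cold_row[key] is not None and warm_row[key] is not None else None)
            for key in cold_row}
    return pd.DataFrame([cold_row, warm_row, diff],
                        index=["cold", "warm", "warm_minus_cold"])
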