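"""Two-stage dFC state detection with correlation-distance k-means.

Stage 1 clusters per-subject exemplar windows (local maxima of connectivity
variance) with many random restarts; stage 2 clusters every window of every
subject, initialized at the stage-1 centroids.  The distance between a
window and a centroid is one minus their Pearson correlation, which is
sensitive to the connectivity *pattern* regardless of overall magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin

from .windows import DFCSeries, select_exemplars


def _standardize_rows(X: np.ndarray, name: str = "row") -> np.ndarray:
    """Center each row and scale to unit norm so corr(x, y) = u_x . u_y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.flatnonzero(norms <= 0)
    if bad.size:
        raise ValueError(f"{name} {int(bad[0])} has zero variance; "
                         "correlation distance is undefined for it")
    return Xc / norms[:, None]


class CorrelationKMeans(BaseEstimator, ClusterMixin):
    """Lloyd's k-means under the correlation distance d(x, c) = 1 - r(x, c).

    Rows are centered and scaled to unit norm, after which the correlation
    is a dot product.  Centroids are updated as the mean of the standardized
    member rows.  An emptied cluster is re-seeded at the point farthest (in
    correlation distance) from its current centroid, which keeps the run
    deterministic for a given ``random_state``.

    Parameters
    ----------
    n_clusters : int
    n_init : int
        Number of random initializations; the solution with the lowest
        total distance (inertia) wins.
    init : 'random' or ndarray (n_clusters, n_features)
        Explicit initial centroids disable the random restarts.
    max_iter, tol : Lloyd iteration controls.
    random_state : seed for the initializations.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) standardized centroids.
    labels_ : 0-based assignment of the training rows.
    inertia_ : total correlation distance of the winning run.
    n_iter_ : iterations of the winning run.
    """

    def __init__(self, n_clusters: int = 4, n_init: int = 10,
                 init="random", max_iter: int = 300, tol: float = 1e-10,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _assign(self, U: np.ndarray, centers: np.ndarray):
        Cs = _standardize_rows(centers, "centroid")
        dist = 1.0 - U @ Cs.T
        labels = np.argmin(dist, axis=1)
        return labels, dist[np.arange(U.shape[0]), labels]

    def _lloyd(self, U: np.ndarray, centers: np.ndarray):
        k = centers.shape[0]
        labels = np.full(U.shape[0], -1)
        inertia = np.inf
        history = []
        for it in range(1, self.max_iter + 1):
            new_labels, d = self._assign(U, centers)
            # re-seed empty clusters at the point farthest from its
            # centroid; stealing a singleton can empty another cluster, so
            # repeat until all k are occupied (bounded by k rounds)
            for _ in range(k):
                empty = [c for c in range(k)
                         if not np.any(new_labels == c)]
                if not empty:
                    break
                for c in empty:
                    far = int(np.argmax(d))
                    new_labels[far] = c
                    d[far] = 0.0
            new_inertia = float(d.sum())
            history.append(new_inertia)
            centers = np.vstack([U[new_labels == c].mean(axis=0)
                                 for c in range(k)])
            if np.array_equal(new_labels, labels) or \
                    inertia - new_inertia < self.tol:
                labels, inertia = new_labels, new_inertia
                break
            labels, inertia = new_labels, new_inertia
        return centers, labels, inertia, it, history

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        n = X.shape[0]
        if n < self.n_clusters:
            raise ValueError(f"{n} rows but n_clusters={self.n_clusters}")
        U = _standardize_rows(X, "row")
        rng = np.random.default_rng(self.random_state)

        if isinstance(self.init, str) and self.init == "random":
            runs = self.n_init
            inits = [U[rng.choice(n, self.n_clusters, replace=False)]
                     for _ in range(runs)]
        else:
            init = np.asarray(self.init, dtype=float)
            if init.shape != (self.n_clusters, X.shape[1]):
                raise ValueError("explicit init has the wrong shape")
            inits = [_standardize_rows(init, "initial centroid")]

        best = None
        for centers0 in inits:
            centers, labels, inertia, n_iter, hist = self._lloyd(
                U, centers0.copy())
            if best is None or inertia < best[2]:
                best = (centers, labels, inertia, n_iter, hist)
        (self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_,
         self.inertia_history_) = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        U = _standardize_rows(np.asarray(X, dtype=float), "row")
        labels, _ = self._assign(U, self.cluster_centers_)
        return labels

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def transform(self, X):
        """Correlation distances to each centroid."""
        U = _standardize_rows(np.asarray(X, dtype=float), "row")
        return 1.0 - U @ _standardize_rows(self.cluster_centers_).T


@dataclass
class ElbowResult:
    k: int
    k_range: np.ndarray
    inertia: np.ndarray
    second_difference: np.ndarray
    weak_elbow: bool


def choose_k_elbow(X, k_range, seed: int | None = None,
                   n_init: int = 20) -> ElbowResult:
    """Pick the cluster count at the elbow of the within-cluster distance.

    The within-cluster total correlation distance W(k) is computed over
    ``k_range``; the elbow is the interior k maximizing the discrete second
    difference W(k-1) - 2 W(k) + W(k+1).  When the strongest second
    difference is below 5% of W(k_min) the curve has no clear elbow and the
    result is flagged ``weak_elbow``.
    """
    ks = np.asarray(sorted(k_range), dtype=int)
    if ks.size < 3:
        raise ValueError("k_range must contain at least 3 values")
    X = np.asarray(X, dtype=float)
    inertia = np.empty(ks.size)
    for i, k in enumerate(ks):
        km = CorrelationKMeans(n_clusters=int(k), n_init=n_init,
                               random_state=None if seed is None
                               else seed + i)
        inertia[i] = km.fit(X).inertia_
    second = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
    best_interior = int(np.argmax(second))
    k_best = int(ks[best_interior + 1])
    weak = bool(second.max() < 0.05 * inertia[0])
    return ElbowResult(k=k_best, k_range=ks, inertia=inertia,
                       second_difference=second, weak_elbow=weak)


@dataclass
class StateModel:
    """K dFC state centroids and per-subject window assignments (1..K)."""

    K: int
    centroids: np.ndarray                      # (K, E)
    assignments: dict[str, np.ndarray]         # subject -> 1..K per window
    inertia: float
    seed: int | None = None
    n_replicates: int = 500
    exemplar_indices: dict[str, np.ndarray] = field(default_factory=dict)
    elbow: ElbowResult | None = None

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([self.assignments[s]
                               for s in sorted(self.assignments)])


def fit_states(dfc_by_subject: dict[str, DFCSeries], k: int,
               seed: int | None = None, n_replicates: int = 500,
               iterate_stage2: bool = True) -> StateModel:
    """Two-stage dFC state clustering over a cohort.

    Stage 1: pool every subject's exemplar windows (local FC-variance
    maxima) and run correlation k-means with ``n_replicates`` random
    restarts.  Stage 2: cluster all windows of all subjects in a single
    k-means run initialized at the stage-1 centroids (full Lloyd iteration
    by default; set ``iterate_stage2=False`` for a pure nearest-centroid
    assignment pass).
    """
    subjects = sorted(dfc_by_subject)
    exemplar_idx = {s: select_exemplars(dfc_by_subject[s]) for s in subjects}
    exemplars = np.vstack([dfc_by_subject[s].values[exemplar_idx[s]]
                           for s in subjects])
    if exemplars.shape[0] < k:
        raise ValueError(f"only {exemplars.shape[0]} exemplars for k={k}")
    stage1 = CorrelationKMeans(n_clusters=k, n_init=n_replicates,
                               random_state=seed).fit(exemplars)

    all_windows = np.vstack([dfc_by_subject[s].values for s in subjects])
    if iterate_stage2:
        stage2 = CorrelationKMeans(n_clusters=k, n_init=1,
                                   init=stage1.cluster_centers_,
                                   random_state=seed).fit(all_windows)
        labels, centroids, inertia = (stage2.labels_, stage2.cluster_centers_,
                                      stage2.inertia_)
    else:
        labels = stage1.predict(all_windows)
        centroids = stage1.cluster_centers_
        inertia = float("nan")

    assignments: dict[str, np.ndarray] = {}
    offset = 0
    for s in subjects:
        w = dfc_by_subject[s].n_windows
        assignments[s] = labels[offset:offset + w] + 1
        offset += w
    return StateModel(K=k, centroids=centroids, assignments=assignments,
                      inertia=float(inertia), seed=seed,
                      n_replicates=n_replicates,
                      exemplar_indices=exemplar_idx)


def match_states(centroids_a: np.ndarray,
                 centroids_b: np.ndarray) -> np.ndarray:
    """Hungarian matching of two centroid sets by pattern correlation.

    Returns ``perm`` such that centroid ``i`` of A matches centroid
    ``perm[i]`` of B, maximizing the summed Pearson correlation.
    """
    A = _standardize_rows(np.asarray(centroids_a, float))
    B = _standardize_rows(np.asarray(centroids_b, float))
    corr = A @ B.T
    _, perm = linear_sum_assignment(-corr)
    return perm
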