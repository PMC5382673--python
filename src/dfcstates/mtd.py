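"""Multiplication of Temporal Derivatives (MTD) coupling analysis.

MTD scores the instantaneous coupling of two components as the product of
their standardized first differences: positive when both series move in the
same direction, negative under anti-coupling.  A short moving average
stabilizes the per-timepoint estimate.  Clustering the per-timepoint
coupling matrices with correlation k-means provides a window-free
confirmation of the sliding-window state analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import CorrelationKMeans
from .panel import TimeCoursePanel


@dataclass
class MTDSeries:
    """Per-timepoint vectorized coupling matrices for one subject.

    ``values`` is (T', E) with E = C(C-1)/2 upper-triangle pairs;
    T' = T - 1 for raw scores and T - w for width-w "valid" smoothing.
    """

    values: np.ndarray
    w: int
    n_components: int
    smoothing: str = "valid"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        E = self.n_components * (self.n_components - 1) // 2
        if self.values.ndim != 2 or self.values.shape[1] != E:
            raise ValueError("values must be (n_timepoints, n_edges)")
        if not np.isfinite(self.values).all():
            raise ValueError("coupling values must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


def moving_average(x: np.ndarray, w: int, axis: int = 0) -> np.ndarray:
    """Simple moving average of width w along ``axis`` ('valid' mode)."""
    if w < 1:
        raise ValueError("w must be at least 1")
    x = np.asarray(x, dtype=float)
    if w == 1:
        return x.copy()
    c = np.cumsum(np.moveaxis(x, axis, 0), axis=0)
    out = np.empty((x.shape[axis] - w + 1,) + c.shape[1:])
    out[0] = c[w - 1]
    out[1:] = c[w:] - c[:-w]
    return np.moveaxis(out / w, 0, axis)


def mtd(panel: TimeCoursePanel, w: int = 15) -> MTDSeries:
    """MTD coupling series for one subject.

    The first difference of each component is z-scored over the whole
    series (mean removed, population sd), pairwise products give the raw
    per-timepoint coupling, and a width-``w`` moving average ("valid" mode)
    smooths it.  ``w=1`` returns the raw scores.
    """
    T, C = panel.data.shape
    if T < w + 2:
        raise ValueError(f"need T >= w + 2 (T={T}, w={w})")
    dt = np.diff(panel.data, axis=0)
    sd = dt.std(axis=0)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(
            f"component {panel.component_ids[int(bad[0])]} has a "
            "zero-variance temporal derivative")
    z = (dt - dt.mean(axis=0)) / sd
    iu = np.triu_indices(C, 1)
    raw = z[:, iu[0]] * z[:, iu[1]]
    smoothed = moving_average(raw, w, axis=0)
    return MTDSeries(values=smoothed, w=w, n_components=C,
                     smoothing="valid", subject_id=panel.subject_id)


def mtd_states(mtd_by_subject: dict[str, MTDSeries], k: int = 4,
               seed: int | None = None, n_init: int = 50):
    """Cluster all subjects' MTD timepoints into k coupling states.

    Shares the correlation-distance k-means of the sliding-window stage.
    Returns ``(assignments, model)`` with per-subject 1..k label vectors.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    subjects = sorted(mtd_by_subject)
    X = np.vstack([mtd_by_subject[s].values for s in subjects])
    if k == 1:
        labels = np.zeros(X.shape[0], dtype=int)
        model = None
    else:
        model = CorrelationKMeans(n_clusters=k, n_init=n_init,
                                  random_state=seed).fit(X)
        labels = model.labels_
    assignments: dict[str, np.ndarray] = {}
    offset = 0
    for s in subjects:
        t = mtd_by_subject[s].n_timepoints
        assignments[s] = labels[offset:offset + t] + 1
        offset += t
    return assignments, model


def spatial_similarity(mtd_by_subject: dict[str, MTDSeries],
                       max_timepoints: int = 500,
                       seed: int | None = None) -> dict:
    """Distribution of pairwise spatial correlations of coupling matrices.

    Pearson correlations between vectorized coupling matrices across all
    timepoints of all subjects.  For tractability at cohort scale a seeded
    random subsample of at most ``max_timepoints`` timepoints is used (the
    full set when it is smaller). Returns summary statistics and the
    similarity matrix of the sampled timepoints.
    """
    X = np.vstack([mtd_by_subject[s].values for s in sorted(mtd_by_subject)])
    if X.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    if X.shape[0] > max_timepoints:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(X.shape[0], max_timepoints, replace=False))
        X = X[idx]
    sim = np.corrcoef(X)
    off = sim[np.triu_indices(sim.shape[0], 1)]
    return {
        "n_timepoints": int(X.shape[0]),
        "mean": float(off.mean()),
        "quantiles": {q: float(np.quantile(off, q))
                      for q in (0.05, 0.25, 0.5, 0.75, 0.95)},
        "similarity": sim,
    }
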