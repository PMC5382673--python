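"""Tapered sliding-window functional connectivity.

Connectivity is estimated in successive tapered windows: the taper is a
rectangle (default 22 TRs) convolved with a Gaussian (default sigma = 3 TRs),
slid in steps of 1 TR.  Within each window a weighted correlation matrix is
computed; an optional L1 penalty on the precision matrix (graphical lasso)
regularizes the estimate.  Exemplar windows — local maxima of the
across-edge connectivity variance — seed the state clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import graphical_lasso

from .panel import TimeCoursePanel

Z_CLIP = 1.0 - 1e-7  # |r| mapped here before atanh to avoid infinities


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing Fisher r-to-z transform, clipped at |r|=1-1e-7."""
    return np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))


def fisher_z_inv(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


@dataclass
class TaperedWindow:
    """Gaussian-tapered rectangular window (weights sum to 1)."""

    weights: np.ndarray
    rect_len: int
    sigma: float
    step: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size != self.rect_len:
            raise ValueError("weights must be a length-rect_len vector")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")


@dataclass
class DFCSeries:
    """Per-subject sequence of vectorized windowed connectivity matrices.

    ``values`` is (W, E) with E = C(C-1)/2 upper-triangle edges in
    ``numpy.triu_indices`` order.
    """

    values: np.ndarray
    window_starts: np.ndarray
    rect_len: int
    step: int
    n_components: int
    fisher_z: bool = False
    lambda_l1: float = 0.0
    subject_id: str = ""
    component_ids: list[str] = field(default_factory=list)
    subnetwork_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        E = self.n_components * (self.n_components - 1) // 2
        if self.values.shape != (self.window_starts.size, E):
            raise ValueError("values must be (n_windows, n_edges)")
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity values must be finite")
        if not self.fisher_z and np.abs(self.values).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("raw correlations must lie in [-1, 1]")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def build_taper(rect_len: int = 22, sigma: float = 3.0,
                kernel_halfwidth: float = 3.0, step: int = 1) -> TaperedWindow:
    """Convolve a unit rectangle with a Gaussian kernel and renormalize.

    ``kernel_halfwidth`` is in units of sigma; the convolution is truncated
    to the ``rect_len`` central samples so the window support stays at
    rect_len. A vanishing sigma recovers the uniform (boxcar) window.
    """
    if rect_len < 2:
        raise ValueError("rect_len must be at least 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h = max(1, int(np.ceil(kernel_halfwidth * sigma)))
    x = np.arange(-h, h + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(rect_len), kernel)  # length rect_len + 2h
    central = full[h:h + rect_len]
    weights = central / central.sum()
    # enforce exact symmetry against floating-point drift in the convolution
    weights = (weights + weights[::-1]) / 2.0
    return TaperedWindow(weights=weights, rect_len=rect_len, sigma=sigma,
                         step=step)


def count_windows(T: int, rect_len: int, step: int = 1) -> int:
    """Number of sliding windows: floor((T - rect_len) / step).

    The convention yields 213 windows for 235 time points with a 22-TR
    window slid in steps of 1 TR.
    """
    if step < 1:
        raise ValueError("step must be at least 1")
    if T <= rect_len:
        raise ValueError(f"T={T} must exceed the window length {rect_len}")
    return (T - rect_len) // step


def _weighted_correlation(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    mu = w @ X
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    degenerate = sd <= 1e-10 * np.maximum(1.0, np.abs(mu))
    if degenerate.any():
        bad = int(np.flatnonzero(degenerate)[0])
        raise ValueError(
            f"singular window covariance: component {bad} has zero variance "
            "in this window; consider lambda_l1 > 0 or longer windows")
    R = cov / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    return np.clip((R + R.T) / 2, -1.0, 1.0)


def windowed_connectivity(panel: TimeCoursePanel,
                          taper: TaperedWindow | None = None,
                          lambda_l1: float = 0.0,
                          fisher: bool = False) -> DFCSeries:
    """Estimate the windowed connectivity series for one subject.

    For each window the taper-weighted correlation matrix is computed; with
    ``lambda_l1 > 0`` a graphical-lasso penalized precision is estimated from
    it and the implied covariance is converted back to correlation. Values
    are vectorized upper triangles, optionally Fisher z-transformed.
    """
    if taper is None:
        taper = build_taper()
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be non-negative")
    T, C = panel.data.shape
    W = count_windows(T, taper.rect_len, taper.step)
    starts = np.arange(W) * taper.step
    iu = np.triu_indices(C, 1)
    out = np.empty((W, iu[0].size))
    for wi, s in enumerate(starts):
        Xw = panel.data[s:s + taper.rect_len]
        R = _weighted_correlation(Xw, taper.weights)
        if lambda_l1 > 0:
            cov, _ = graphical_lasso(R, alpha=lambda_l1, max_iter=200)
            d = np.sqrt(np.diag(cov))
            R = cov / np.outer(d, d)
            np.fill_diagonal(R, 1.0)
            R = np.clip(R, -1.0, 1.0)
        out[wi] = R[iu]
    values = fisher_z(out) if fisher else out
    return DFCSeries(values=values, window_starts=starts,
                     rect_len=taper.rect_len, step=taper.step,
                     n_components=C, fisher_z=fisher, lambda_l1=lambda_l1,
                     subject_id=panel.subject_id,
                     component_ids=list(panel.component_ids),
                     subnetwork_labels=list(panel.subnetwork_labels))


def select_exemplars(series: DFCSeries | np.ndarray) -> np.ndarray:
    """Window indices at strict local maxima of the across-edge FC variance.

    The variance across the E edge values is computed per window; strict
    interior local maxima are returned (a plateau contributes its first
    index only). If no interior maximum exists the global maximum is
    returned as a fallback.  Indices are 0-based.
    """
    values = series.values if isinstance(series, DFCSeries) else np.asarray(series)
    if values.ndim == 2:
        var = values.var(axis=1)
    else:
        var = values.astype(float)
    W = var.size
    if W < 3:
        raise ValueError("need at least 3 windows to find local maxima")
    peaks = []
    i = 1
    while i < W - 1:
        if var[i] > var[i - 1]:
            j = i
            while j + 1 < W and var[j + 1] == var[i]:
                j += 1
            if j < W - 1 and var[j + 1] < var[i]:
                peaks.append(i)  # plateau start
            i = j + 1
        else:
            i += 1
    if not peaks:
        return np.array([int(np.argmax(var))])
    return np.asarray(peaks, dtype=int)


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: TimeCoursePanel -> (W, E) connectivity.

    Parameters mirror the windowing defaults: 22-TR rectangle, Gaussian
    taper sigma = 3 TRs, step 1 TR, optional L1 precision penalty.
    """

    def __init__(self, rect_len: int = 22, sigma: float = 3.0, step: int = 1,
                 lambda_l1: float = 0.0, fisher: bool = False):
        self.rect_len = rect_len
        self.sigma = sigma
        self.step = step
        self.lambda_l1 = lambda_l1
        self.fisher = fisher

    def fit(self, X=None, y=None):
        self.taper_ = build_taper(self.rect_len, self.sigma, step=self.step)
        return self

    def transform(self, panel: TimeCoursePanel) -> DFCSeries:
        if not hasattr(self, "taper_"):
            self.fit()
        return windowed_connectivity(panel, self.taper_,
                                     lambda_l1=self.lambda_l1,
                                     fisher=self.fisher)
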