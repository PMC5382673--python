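"""Post-ICA cleaning of component time courses.

The cleaning chain mirrors standard dFC practice: polynomial detrend
(up to cubic), zero-phase low-pass filtering at 0.15 Hz, multiple regression
of head-motion parameters, and replacement of detected outlier time points
with a third-order spline fitted through the clean portion of the series.
A framewise-displacement summary supports motion QC.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import MotionParams, TimeCoursePanel

HEAD_RADIUS_MM = 50.0  # sphere radius used to convert rotations to mm


def detrend_poly(panel: TimeCoursePanel, max_order: int = 3) -> TimeCoursePanel:
    """Remove polynomial trends up to ``max_order`` (1=linear..3=cubic).

    Projects each column onto the orthogonal complement of the polynomial
    basis {1, t, ..., t^max_order}; the output is mean-free and orthogonal
    to every basis member.
    """
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2 or 3")
    T = panel.n_timepoints
    if T <= max_order + 1:
        raise ValueError(f"series too short (T={T}) for order-{max_order} detrend")
    t = np.linspace(-1.0, 1.0, T)
    basis = np.polynomial.legendre.legvander(t, max_order)  # well-conditioned
    Q, _ = np.linalg.qr(basis)
    resid = panel.data - Q @ (Q.T @ panel.data)
    return panel.with_data(resid)


def lowpass(panel: TimeCoursePanel, cutoff_hz: float = 0.15,
            order: int = 4) -> TimeCoursePanel:
    """Zero-phase Butterworth low-pass filter (forward-backward)."""
    nyquist = 1.0 / (2.0 * panel.tr_seconds)
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    b, a = butter(order, cutoff_hz / nyquist, btype="low")
    return panel.with_data(filtfilt(b, a, panel.data, axis=0))


def regress_nuisance(panel: TimeCoursePanel,
                     regressors: np.ndarray) -> TimeCoursePanel:
    """Regress out nuisance time series (plus an intercept) from each column.

    Collinear regressor columns are handled by a pseudo-inverse solve and a
    warning; the residuals are orthogonal to the retained column space.
    """
    R = np.asarray(regressors, dtype=float)
    if R.ndim != 2 or R.shape[0] != panel.n_timepoints:
        raise ValueError("regressors must be (T, q) matching the panel")
    if R.shape[1] >= panel.n_timepoints:
        raise ValueError("more regressors than time points")
    X = np.column_stack([np.ones(panel.n_timepoints), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient ({rank}/{X.shape[1]}); "
            "collinear columns contribute nothing", stacklevel=2)
    beta = np.linalg.pinv(X) @ panel.data
    return panel.with_data(panel.data - X @ beta)


def _detect_spikes(col: np.ndarray, mad_thresh: float) -> np.ndarray:
    """Flag spike time points via a robust z-score on the first difference.

    Outlying first differences implicate the time points on either side;
    the candidates are then confirmed by comparing each against a linear
    interpolation from its nearest clean neighbours, so a step's clean
    shoulder is not flagged along with the spike itself.
    """
    T = col.size
    d = np.diff(col)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad < 1e-12 * max(1.0, np.abs(col).max()):
        return np.zeros(T, dtype=bool)
    z = 0.6745 * (d - med) / mad
    bad_diff = np.abs(z) > mad_thresh
    candidates = np.zeros(T, dtype=bool)
    idx = np.flatnonzero(bad_diff)  # diff t is col[t+1]-col[t]
    candidates[idx] = True
    candidates[idx + 1] = True
    if not candidates.any():
        return candidates
    clean_idx = np.flatnonzero(~candidates)
    if clean_idx.size < 2:
        return candidates
    sigma = 1.4826 * mad / np.sqrt(2.0)  # noise sd implied by the diff MAD
    confirmed = np.zeros(T, dtype=bool)
    interp = np.interp(np.flatnonzero(candidates), clean_idx, col[clean_idx])
    for p, est in zip(np.flatnonzero(candidates), interp):
        if np.abs(col[p] - est) > mad_thresh * sigma:
            confirmed[p] = True
    return confirmed


def despike_spline(panel: TimeCoursePanel, mad_thresh: float = 3.5):
    """Detect outlier time points and replace them with cubic-spline estimates.

    Returns ``(panel, mask)`` where ``mask`` is a boolean (T, C) array of
    replaced points. Non-flagged samples are untouched. A column with more
    than half of its points flagged is considered unusable and raises.
    """
    if mad_thresh <= 0:
        raise ValueError("mad_thresh must be positive")
    data = panel.data.copy()
    T, C = data.shape
    mask = np.zeros((T, C), dtype=bool)
    t = np.arange(T)
    for c in range(C):
        flags = _detect_spikes(data[:, c], mad_thresh)
        if flags.sum() > T / 2:
            raise ValueError(
                f"component {panel.component_ids[c]}: more than 50% of "
                "points flagged as outliers; signal unusable")
        if flags.any():
            clean = ~flags
            spline = CubicSpline(t[clean], data[clean, c])
            data[flags, c] = spline(t[flags])
            mask[:, c] = flags
    return panel.with_data(data), mask


def framewise_displacement(motion: MotionParams,
                           head_radius_mm: float = HEAD_RADIUS_MM):
    """Framewise displacement: sum of absolute parameter changes per frame.

    FD(t) = sum_i |d trans_i| + r * sum_j |d rot_j|, with rotations converted
    to arc length on a sphere of radius ``head_radius_mm``. Returns the
    length T-1 series and its mean.
    """
    d = np.abs(np.diff(motion.data, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd, float(fd.mean()) if fd.size else 0.0


class TimeCourseCleaner(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying the full cleaning chain.

    Order: detrend -> low-pass -> nuisance regression -> despike. Any step
    can be switched off. ``transform`` accepts a TimeCoursePanel and an
    optional MotionParams and returns the cleaned panel; the outlier mask of
    the last transform is kept in ``outlier_mask_``.
    """

    def __init__(self, max_order: int = 3, cutoff_hz: float = 0.15,
                 mad_thresh: float = 3.5, detrend: bool = True,
                 filter: bool = True, regress_motion: bool = True,
                 despike: bool = True):
        self.max_order = max_order
        self.cutoff_hz = cutoff_hz
        self.mad_thresh = mad_thresh
        self.detrend = detrend
        self.filter = filter
        self.regress_motion = regress_motion
        self.despike = despike

    def fit(self, X=None, y=None):
        # stateless: cleaning has no parameters to learn
        self.n_features_in_ = X.n_components if isinstance(
            X, TimeCoursePanel) else None
        return self

    def transform(self, panel: TimeCoursePanel,
                  motion: MotionParams | None = None) -> TimeCoursePanel:
        out = panel
        if self.detrend:
            out = detrend_poly(out, self.max_order)
        if self.filter:
            out = lowpass(out, self.cutoff_hz)
        if self.regress_motion and motion is not None:
            if motion.n_timepoints != out.n_timepoints:
                raise ValueError("motion length does not match panel")
            out = regress_nuisance(out, motion.data)
        if self.despike:
            out, mask = despike_spline(out, self.mad_thresh)
            self.outlier_mask_ = mask
        else:
            self.outlier_mask_ = np.zeros(out.data.shape, dtype=bool)
        return out
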