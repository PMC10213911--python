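"""Smoothing and photobleaching compensation for ICP recordings.

Profiles are smoothed with a third-order Savitzky-Golay filter over an
11-sample window before any event analysis. Prolonged excitation bleaches
Fura-2, which appears as a common negative linear trend; the trend is
estimated as the mean ordinary-least-squares slope of the 20 lowest-
variability profiles and subtracted from every trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import Recording, ValidationError

__all__ = [
    "BleachModel",
    "SavGolSmoother",
    "BleachCompensator",
    "smooth_traces",
    "estimate_mean_bleach_slope",
    "compensate_bleach",
]


@dataclass(frozen=True)
class BleachModel:
    """Global photobleaching drift model.

    ``mean_slope`` is in ratio units per second; ``contributing_cell_ids``
    are the lowest-standard-deviation profiles whose OLS slopes were
    averaged (event-rich traces have high variance and are excluded by the
    ranking).
    """

    mean_slope: float
    contributing_cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_slope):
            raise ValidationError("bleach slope must be finite")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, Recording):
        return X.traces
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


class SavGolSmoother(TransformerMixin, BaseEstimator):
    """Savitzky-Golay least-squares local-polynomial smoother.

    Stateless transformer; ``fit`` only validates. Edge samples are
    evaluated from a polynomial fitted at each end of the trace (no signal
    extension), so no pre/post-recording samples are fabricated that could
    create spurious boundary extrema.

    Parameters
    ----------
    window : int, default 11
        Odd window length in samples.
    polyorder : int, default 3
        Polynomial order; must be < window.
    """

    def __init__(self, window: int = 11, polyorder: int = 3):
        self.window = window
        self.polyorder = polyorder

    def _validate(self, n_frames: int) -> None:
        if self.window % 2 == 0:
            raise ValidationError("smoothing window must be odd")
        if self.window > n_frames:
            raise ValidationError("smoothing window exceeds trace length")
        if self.polyorder >= self.window:
            raise ValidationError("polyorder must be smaller than window")

    def fit(self, X, y=None):
        self._validate(_as_matrix(X).shape[1])
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        mat = _as_matrix(X)
        self._validate(mat.shape[1])
        out = savgol_filter(mat, self.window, self.polyorder,
                            axis=1, mode="interp")
        if isinstance(X, Recording):
            return Recording(out, X.cell_ids, X.sample_period_s,
                             smoothed=True,
                             bleach_compensated=X.bleach_compensated)
        return out


class BleachCompensator(TransformerMixin, BaseEstimator):
    """Remove the common linear photobleaching trend.

    ``fit`` ranks traces by standard deviation, OLS-fits a line (ratio vs
    time in seconds) to each of the ``n_lowest`` quietest traces and stores
    the mean slope; ``transform`` adds ``-slope * (t - t0)`` to every trace,
    anchored at the first frame so baseline levels are preserved.

    Attributes
    ----------
    mean_slope_ : float
        Mean OLS slope, ratio units per second.
    contributing_indices_ : ndarray
        Row indices of the traces used for the estimate.
    """

    def __init__(self, n_lowest: int = 20, sample_period_s: float | None = None):
        self.n_lowest = n_lowest
        self.sample_period_s = sample_period_s

    def _period(self, X) -> float:
        if isinstance(X, Recording):
            return X.sample_period_s
        if self.sample_period_s is None:
            raise ValidationError(
                "sample_period_s is required when X is a bare matrix")
        return self.sample_period_s

    def fit(self, X, y=None):
        mat = _as_matrix(X)
        ts = self._period(X)
        n = min(self.n_lowest, mat.shape[0])
        order = np.argsort(mat.std(axis=1), kind="stable")[:n]
        t = np.arange(mat.shape[1]) * ts
        # OLS slope per selected trace: cov(t, y) / var(t)
        tc = t - t.mean()
        denom = float(tc @ tc)
        slopes = (mat[order] @ tc) / denom
        self.contributing_indices_ = order
        self.mean_slope_ = float(slopes.mean())
        self.n_features_in_ = mat.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_slope_")
        mat = _as_matrix(X)
        t = np.arange(mat.shape[1]) * self._period(X)
        out = mat - self.mean_slope_ * (t - t[0])
        if isinstance(X, Recording):
            return Recording(out, X.cell_ids, X.sample_period_s,
                             smoothed=X.smoothed, bleach_compensated=True)
        return out

    def model_(self, X) -> BleachModel:
        check_is_fitted(self, "mean_slope_")
        if isinstance(X, Recording):
            ids = tuple(X.cell_ids[i] for i in self.contributing_indices_)
        else:
            ids = tuple(str(i) for i in self.contributing_indices_)
        return BleachModel(self.mean_slope_, ids)


def smooth_traces(rec: Recording, window: int = 11, polyorder: int = 3) -> Recording:
    """Smooth every profile; see :class:`SavGolSmoother`."""
    return SavGolSmoother(window, polyorder).fit(rec).transform(rec)


def estimate_mean_bleach_slope(rec: Recording, n_lowest: int = 20) -> BleachModel:
    """Mean OLS slope (a.u./s) of the ``n_lowest`` quietest profiles."""
    comp = BleachCompensator(n_lowest=n_lowest).fit(rec)
    return comp.model_(rec)


def compensate_bleach(rec: Recording, model: BleachModel) -> Recording:
    """Subtract the global drift ``model.mean_slope * (t - t0)``."""
    comp = BleachCompensator()
    comp.mean_slope_ = model.mean_slope
    comp.contributing_indices_ = np.empty(0, dtype=int)
    return comp.transform(rec)
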