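"""ROI time-series containers and conditioning.

Standard resting-state conditioning for region-averaged fMRI matrices:
zero-phase bandpass filtering to the band where the BOLD signal lives,
global signal regression, two-axis z-normalization, and segmentation into
fixed-length contiguous chunks for recurrent training.

All transformers follow the scikit-learn transformer protocol and operate
on plain ``(T, M)`` arrays (frames by regions); the module-level functions
wrap them for :class:`ROITimeSeries` objects and keep a provenance trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ROITimeSeries",
    "SegmentSet",
    "BandpassFilter",
    "GlobalSignalRegressor",
    "TwoAxisZScorer",
    "bandpass",
    "global_signal_regress",
    "znormalize",
    "segment",
]

DEFAULT_BAND_HZ = (0.008, 0.125)


@dataclass
class ROITimeSeries:
    """T x M region-averaged signal with its repetition time.

    ``data[t, i]`` is the signal of region ``i`` at frame ``t``; ``tr_s``
    is the sampling interval (repetition time) in seconds.
    """

    data: np.ndarray
    tr_s: float = 0.72
    roi_labels: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError(f"time series must be 2-D (T, M), got shape {d.shape}")
        if d.shape[0] < 2:
            raise ValueError("need at least two frames")
        if not np.all(np.isfinite(d)):
            raise ValueError("time series contains non-finite entries")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        self.data = d
        if not self.roi_labels:
            self.roi_labels = [f"ROI_{i:03d}" for i in range(d.shape[1])]
        if len(self.roi_labels) != d.shape[1]:
            raise ValueError("roi_labels length does not match number of columns")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.tr_s

    def _derive(self, data: np.ndarray, step: str) -> "ROITimeSeries":
        return ROITimeSeries(
            data=data,
            tr_s=self.tr_s,
            roi_labels=list(self.roi_labels),
            provenance=list(self.provenance) + [step],
        )


@dataclass
class SegmentSet:
    """Contiguous, non-overlapping L-frame chunks of one scan."""

    segments: list[np.ndarray]
    L: int
    spans: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.segments)


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth bandpass along the time axis.

    A 4th-order Butterworth applied forward and backward (``sosfiltfilt``)
    gives a zero-phase band-limited output — phase distortion would shift
    events in time, which matters for template-based pattern analyses.
    With ``lo_hz=0`` the filter degenerates to a pure lowpass.
    """

    def __init__(self, lo_hz: float = DEFAULT_BAND_HZ[0],
                 hi_hz: float = DEFAULT_BAND_HZ[1], tr_s: float = 0.72,
                 order: int = 4):
        self.lo_hz = lo_hz
        self.hi_hz = hi_hz
        self.tr_s = tr_s
        self.order = order

    def fit(self, X, y=None):
        self._validate(np.asarray(X))
        return self

    def _validate(self, X: np.ndarray) -> None:
        nyq = 0.5 / self.tr_s
        if not (0.0 <= self.lo_hz < self.hi_hz):
            raise ValueError("need 0 <= lo_hz < hi_hz")
        if self.hi_hz >= nyq:
            raise ValueError(
                f"hi_hz={self.hi_hz} must be below the Nyquist frequency {nyq:.4g}"
            )

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        self._validate(X)
        fs = 1.0 / self.tr_s
        if self.lo_hz <= 0.0:
            sos = scipy.signal.butter(self.order, self.hi_hz, btype="lowpass",
                                      fs=fs, output="sos")
        else:
            sos = scipy.signal.butter(self.order, [self.lo_hz, self.hi_hz],
                                      btype="bandpass", fs=fs, output="sos")
        return scipy.signal.sosfiltfilt(sos, X, axis=0)


class GlobalSignalRegressor(BaseEstimator, TransformerMixin):
    """Remove the cortex-wide mean time course from every region.

    Each column is regressed (ordinary least squares, with intercept) on
    the mean time course across all regions; the residuals are returned.
    Residuals are orthogonal to the global regressor by construction.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] <= 2:
            raise ValueError("need more than two frames for regression")
        g = X.mean(axis=1)
        if np.std(g) <= 1e-12 * max(1.0, abs(g.mean())):
            raise ValueError("global signal has zero variance")
        design = np.column_stack([np.ones_like(g), g])
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        return X - design @ beta


class TwoAxisZScorer(BaseEstimator, TransformerMixin):
    """Two-pass standardization: each region over time, then each frame across regions.

    Pass 1 gives every region zero mean and unit variance over the scan;
    pass 2 standardizes every frame across regions, removing frame-wide
    offsets.  A series that is already standardized along both axes is a
    fixed point.  The frame-axis pass slightly perturbs the per-column
    statistics of pass 1; with many regions the perturbation is small.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0)
        tiny = 1e-12 * np.maximum(1.0, np.abs(X.mean(axis=0)))
        if np.any(sd <= tiny):
            raise ValueError("constant column: cannot z-normalize over time")
        X = (X - X.mean(axis=0)) / sd
        fsd = X.std(axis=1, keepdims=True)
        if np.any(fsd <= 1e-12):
            raise ValueError("constant frame: cannot z-normalize across regions")
        return (X - X.mean(axis=1, keepdims=True)) / fsd


def bandpass(ts: ROITimeSeries, lo_hz: float = DEFAULT_BAND_HZ[0],
             hi_hz: float = DEFAULT_BAND_HZ[1]) -> ROITimeSeries:
    """Zero-phase bandpass of a time series; see :class:`BandpassFilter`."""
    out = BandpassFilter(lo_hz=lo_hz, hi_hz=hi_hz, tr_s=ts.tr_s).transform(ts.data)
    return ts._derive(out, f"bandpass[{lo_hz}-{hi_hz}Hz]")


def global_signal_regress(ts: ROITimeSeries) -> ROITimeSeries:
    """Global signal regression; see :class:`GlobalSignalRegressor`."""
    out = GlobalSignalRegressor().transform(ts.data)
    return ts._derive(out, "gsr")


def znormalize(ts: ROITimeSeries) -> ROITimeSeries:
    """Two-axis z-normalization (time axis first, then frame axis)."""
    out = TwoAxisZScorer().transform(ts.data)
    return ts._derive(out, "znorm[time,frame]")


def segment(ts: ROITimeSeries, L: int) -> SegmentSet:
    """Cut a scan into ``floor(T / L)`` contiguous non-overlapping chunks.

    Trailing remainder frames are dropped: recurrent training needs
    full-length sequences, and zero-padding would plant spurious dynamics.
    """
    if L <= 1:
        raise ValueError("segment length must exceed 1")
    T = ts.n_frames
    if T < L:
        raise ValueError(f"scan of {T} frames is shorter than segment length {L}")
    n = T // L
    segs = [ts.data[i * L:(i + 1) * L] for i in range(n)]
    spans = [(i * L, (i + 1) * L) for i in range(n)]
    return SegmentSet(segments=segs, L=L, spans=spans)
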