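"""Evaluation metrics for predicted and simulated whole-brain signals.

Forecast accuracy (coefficient of determination per recursive step,
mean squared error per region), static functional connectivity and its
similarity across models, the 1/f spectral slope of the band-limited
signal, and the persistence null forecaster that simply repeats the last
observed frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .preprocess import ROITimeSeries

__all__ = [
    "FCMatrix",
    "r2_per_step",
    "r2_score_pooled",
    "mse_per_roi",
    "fc",
    "fc_similarity",
    "power_slope",
    "persistence_forecast",
]


@dataclass
class FCMatrix:
    """Pearson correlation matrix between region time courses."""

    values: np.ndarray
    ordering: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]


def _as_data(ts) -> np.ndarray:
    return ts.data if isinstance(ts, ROITimeSeries) else np.asarray(ts, dtype=float)


def r2_score_pooled(predicted: np.ndarray, actual: np.ndarray) -> float:
    """R^2 per region over pooled frames, averaged (unweighted) across regions.

    ``1 - SSE/SST`` per region, with SST around the region's own mean over
    the pooled evaluation frames.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("shape mismatch between predicted and actual")
    p = predicted.reshape(-1, predicted.shape[-1])
    a = actual.reshape(-1, actual.shape[-1])
    sst = np.sum((a - a.mean(axis=0)) ** 2, axis=0)
    if np.any(sst == 0):
        raise ValueError("zero-variance actual signal in at least one region")
    sse = np.sum((a - p) ** 2, axis=0)
    return float(np.mean(1.0 - sse / sst))


def r2_per_step(predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """R^2 at each forecast horizon.

    ``predicted`` and ``actual`` have shape (H, M, N) — horizon steps by
    regions by evaluation instances (pooled across segments/scans) — or
    (H, M) for a single instance.  Returns a length-H vector: per region
    R^2 over the pooled instances at that step, averaged across regions.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("shape mismatch between predicted and actual")
    if predicted.ndim == 2:
        predicted = predicted[..., None]
        actual = actual[..., None]
    H = predicted.shape[0]
    out = np.empty(H)
    for h in range(H):
        out[h] = r2_score_pooled(predicted[h].T, actual[h].T)
    return out


def mse_per_roi(predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Mean squared error per region (pooled over all other axes)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("shape mismatch between predicted and actual")
    r = (predicted - actual).reshape(-1, predicted.shape[-1])
    return np.mean(r ** 2, axis=0)


def fc(ts) -> FCMatrix:
    """Static functional connectivity: Pearson correlation between regions."""
    data = _as_data(ts)
    if data.shape[0] < 3:
        raise ValueError("need at least three frames for a correlation matrix")
    if np.any(data.std(axis=0) == 0):
        raise ValueError("constant region: correlation undefined")
    values = np.corrcoef(data.T)
    labels = list(ts.roi_labels) if isinstance(ts, ROITimeSeries) else []
    return FCMatrix(values=values, ordering=labels)


def fc_similarity(a: FCMatrix, b: FCMatrix) -> float:
    """Pearson correlation of the strict upper triangles of two FC matrices."""
    if a.n_rois != b.n_rois:
        raise ValueError("FC matrices have different sizes")
    if a.ordering and b.ordering and a.ordering != b.ordering:
        raise ValueError("FC matrices have different region orderings")
    ua, ub = a.upper_triangle(), b.upper_triangle()
    return float(np.corrcoef(ua, ub)[0, 1])


def power_slope(
    ts,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
    nperseg: int = 128,
    tr_s: float | None = None,
):
    """Average power spectrum and its 1/f slope in ``[f_lo, f_hi]``.

    Welch periodograms (128-frame segments, 50% overlap) per region are
    averaged across regions; the slope is ``-d log10(P) / d log10(f)``
    fitted by least squares inside the band, so a ``1/f^0.9`` spectrum
    yields a slope of 0.9.  Returns ``(freqs, spectrum, slope)``.

    A narrowband (line-dominated) spectrum has no meaningful broadband
    slope: if a single frequency bin carries most of the band power the
    fit is rejected with a warning and the slope is NaN.
    """
    data = _as_data(ts)
    if tr_s is None:
        tr_s = ts.tr_s if isinstance(ts, ROITimeSeries) else 0.72
    fs = 1.0 / tr_s
    nperseg = min(nperseg, data.shape[0])
    freqs, pxx = scipy.signal.welch(data, fs=fs, nperseg=nperseg, axis=0)
    spectrum = pxx.mean(axis=1)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if band.sum() < 8:
        raise ValueError(
            "fewer than 8 frequency bins in the fitting band; use a longer "
            "series or a wider band"
        )
    pb = spectrum[band]
    if np.max(pb) > 0.5 * np.sum(pb):
        warnings.warn(
            "band power is dominated by a single frequency bin; broadband "
            "1/f slope fit rejected",
            RuntimeWarning,
            stacklevel=2,
        )
        return freqs, spectrum, float("nan")
    x = np.log10(freqs[band])
    y = np.log10(pb)
    slope = -np.polyfit(x, y, 1)[0]
    return freqs, spectrum, float(slope)


def persistence_forecast(segment: np.ndarray, horizon: int) -> np.ndarray:
    """Null forecaster: every future frame equals the last observed frame."""
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    seg = _as_data(segment)
    return np.tile(seg[-1], (horizon, 1))
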