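"""Dynamical analyses of whole-brain time series.

Two complementary views of the minute-scale structure of resting-state
signals:

* **Quasiperiodic patterns (QPP)** — a ~20 s spatiotemporal template that
  recurs throughout the scan, found by iterative template matching: seed
  with a random segment, correlate it with the signal at every lag, average
  the windows at the correlation peaks into a new template, repeat to
  convergence.  Occurrence is counted against a phase-randomized surrogate
  null.
* **Sliding-window FC states** — short-window (~36 s) functional
  connectivity matrices, Fisher z-transformed, clustered with L1 k-means
  (implemented as k-medians, since medians are the L1-optimal centers);
  characterized by dwell times and transition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .preprocess import ROITimeSeries

__all__ = [
    "QPPTemplate",
    "WindowedFCStack",
    "StateModel",
    "detect_qpp",
    "occurrence_rate",
    "phase_align",
    "sliding_fc",
    "cluster_states",
    "dwell_and_transitions",
    "QPPDetector",
    "FCStateClusterer",
]


# --------------------------------------------------------------------- #
# quasiperiodic patterns                                                #
# --------------------------------------------------------------------- #


@dataclass
class QPPTemplate:
    """W x M repeating spatiotemporal pattern and its sliding-correlation trace.

    ``corr_trace[t]`` is the correlation of the template with the signal
    window starting at frame ``t`` (one entry per valid window start,
    i.e. length ``T - W + 1``).
    """

    pattern: np.ndarray
    corr_trace: np.ndarray
    window_frames: int
    n_iterations: int = 0
    score: float = 0.0
    occurrence_rate: float | None = None
    threshold: float | None = None


def _standardize_rois(window: np.ndarray) -> np.ndarray:
    """Standardize each region's trace within a W x M window (zero-safe)."""
    mu = window.mean(axis=0)
    sd = window.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (window - mu) / sd


def _corr_trace(template: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Sliding template correlation: mean per-region correlation at each lag."""
    W, M = template.shape
    tz = _standardize_rois(template)
    win = sliding_window_view(data, W, axis=0)  # (L, M, W)
    mu = win.mean(axis=2)
    sd = win.std(axis=2)
    num = np.einsum("lmw,wm->lm", win, tz) / W - mu * tz.mean(axis=0)
    valid = sd > 0
    corr = np.zeros_like(num)
    np.divide(num, sd, out=corr, where=valid)
    return corr.mean(axis=1)


def _template_peaks(trace: np.ndarray, threshold: float, distance: int) -> np.ndarray:
    peaks, _ = scipy.signal.find_peaks(trace, height=threshold, distance=distance)
    return peaks


def detect_qpp(
    ts,
    window_s: float = 20.0,
    n_random_starts: int = 10,
    max_iter: int = 20,
    seed: int | np.random.Generator | None = None,
    entry_threshold: tuple[float, float] = (0.1, 0.2),
    convergence_corr: float = 0.9999,
) -> QPPTemplate:
    """Detect the dominant quasiperiodic pattern by iterative template matching.

    For each random start: take a W-frame segment as the candidate
    template, correlate it with the signal at every lag, locate local
    correlation maxima above the entry threshold (0.1 on the first
    iteration, 0.2 thereafter), average the signal windows at those maxima
    into the next template, and iterate until consecutive templates
    correlate above ``convergence_corr`` or ``max_iter`` is reached.  The
    start whose final template has the highest summed peak correlation
    wins.

    The input should be z-scored and band-limited; typical usage filters
    to 0.008–0.125 Hz first.
    """
    data = ts.data if isinstance(ts, ROITimeSeries) else np.asarray(ts, dtype=float)
    tr = ts.tr_s if isinstance(ts, ROITimeSeries) else 0.72
    W = int(round(window_s / tr))
    T = data.shape[0]
    if T < 3 * W:
        raise ValueError(f"scan of {T} frames too short for {W}-frame templates")
    if np.any(data.std(axis=0) == 0):
        raise ValueError("constant region: template correlation undefined")
    rng = np.random.default_rng(seed)

    best: QPPTemplate | None = None
    starts = rng.integers(0, T - W + 1, size=n_random_starts)
    for s0 in starts:
        template = data[s0 : s0 + W].copy()
        n_it = 0
        trace = _corr_trace(template, data)
        for it in range(max_iter):
            thr = entry_threshold[0] if it == 0 else entry_threshold[1]
            peaks = _template_peaks(trace, thr, W)
            if peaks.size == 0:
                break
            new_template = np.mean([data[p : p + W] for p in peaks], axis=0)
            n_it = it + 1
            flat_corr = np.corrcoef(template.ravel(), new_template.ravel())[0, 1]
            template = new_template
            trace = _corr_trace(template, data)
            if flat_corr >= convergence_corr:
                break
        peaks = _template_peaks(trace, entry_threshold[1], W)
        score = float(trace[peaks].sum()) if peaks.size else 0.0
        cand = QPPTemplate(
            pattern=template,
            corr_trace=trace,
            window_frames=W,
            n_iterations=n_it,
            score=score,
        )
        if best is None or cand.score > best.score:
            best = cand
    return best


def phase_randomized_surrogate(
    data: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Amplitude-preserving phase-randomized surrogate.

    The same random phase shifts are applied to every region, preserving
    each region's power spectrum and the full cross-covariance structure —
    a stationary linear null for pattern-occurrence testing.
    """
    T = data.shape[0]
    F = np.fft.rfft(data, axis=0)
    phases = rng.uniform(0, 2 * np.pi, size=F.shape[0])
    phases[0] = 0.0
    if T % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(F * np.exp(1j * phases)[:, None], n=T, axis=0)


def occurrence_rate(
    template: QPPTemplate,
    ts,
    alpha: float = 0.05,
    n_surrogates: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Template occurrences per minute, thresholded against a surrogate null.

    The significance threshold is the ``1 - alpha`` quantile of the local
    correlation maxima pooled over phase-randomized surrogates of the
    scan; the rate is the count of suprathreshold local maxima of the real
    correlation trace divided by the scan duration in minutes.  Updates
    ``template.occurrence_rate`` and ``template.threshold`` in place.
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates for a stable threshold")
    data = ts.data if isinstance(ts, ROITimeSeries) else np.asarray(ts, dtype=float)
    tr = ts.tr_s if isinstance(ts, ROITimeSeries) else 0.72
    if data.shape[1] != template.pattern.shape[1]:
        raise ValueError("template and scan have different numbers of regions")
    W = template.window_frames
    rng = np.random.default_rng(seed)
    null_peaks: list[np.ndarray] = []
    for _ in range(n_surrogates):
        surr = phase_randomized_surrogate(data, rng)
        trace = _corr_trace(template.pattern, surr)
        p, _ = scipy.signal.find_peaks(trace, distance=W)
        null_peaks.append(trace[p])
    pooled = np.concatenate(null_peaks)
    threshold = float(np.quantile(pooled, 1.0 - alpha))
    trace = _corr_trace(template.pattern, data)
    peaks = _template_peaks(trace, threshold, W)
    minutes = data.shape[0] * tr / 60.0
    rate = peaks.size / minutes
    template.occurrence_rate = rate
    template.threshold = threshold
    template.corr_trace = trace
    return rate


def phase_align(a: np.ndarray, b: np.ndarray) -> tuple[int, float]:
    """Best circular time shift of ``a`` against ``b`` (flattened Pearson).

    Returns ``(shift, max_corr)`` where rolling ``a`` forward by ``shift``
    frames maximizes the correlation with ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patterns must have the same shape")
    W = a.shape[0]
    bf = b.ravel()
    best_shift, best_corr = 0, -np.inf
    for s in range(W):
        corr = np.corrcoef(np.roll(a, s, axis=0).ravel(), bf)[0, 1]
        if corr > best_corr:
            best_shift, best_corr = s, float(corr)
    return best_shift, best_corr


# --------------------------------------------------------------------- #
# sliding-window FC states                                              #
# --------------------------------------------------------------------- #


@dataclass
class WindowedFCStack:
    """Fisher z-transformed sliding-window FC matrices with their start frames."""

    matrices: np.ndarray  # (Nw, M, M)
    window_s: float
    step_frames: int
    starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_rois(self) -> int:
        return self.matrices.shape[1]

    def vectorized(self) -> np.ndarray:
        """Strict upper triangles, shape (Nw, M*(M-1)/2)."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.matrices[:, iu[0], iu[1]]


def sliding_fc(ts, window_s: float = 36.0, step_frames: int = 1) -> WindowedFCStack:
    """Sliding-window functional connectivity, Fisher z-transformed.

    Windows of ``window_s`` seconds (rounded to frames) advance by
    ``step_frames``; each window's Pearson FC is mapped through
    ``atanh`` with correlations clipped to ``|r| <= 1 - 1e-6``.
    """
    data = ts.data if isinstance(ts, ROITimeSeries) else np.asarray(ts, dtype=float)
    tr = ts.tr_s if isinstance(ts, ROITimeSeries) else 0.72
    W = int(round(window_s / tr))
    T = data.shape[0]
    if W > T:
        raise ValueError(f"window of {W} frames longer than scan of {T} frames")
    if step_frames < 1:
        raise ValueError("step_frames must be at least 1")
    starts = np.arange(0, T - W + 1, step_frames)
    mats = np.empty((starts.size, data.shape[1], data.shape[1]))
    for i, s in enumerate(starts):
        r = np.corrcoef(data[s : s + W].T)
        mats[i] = np.arctanh(np.clip(r, -1 + 1e-6, 1 - 1e-6))
    return WindowedFCStack(
        matrices=mats, window_s=W * tr, step_frames=step_frames, starts=starts
    )


@dataclass
class StateModel:
    """k FC cluster centers with window labels and transition statistics.

    Labels are 1-based (1..k).  ``dwell_times_s`` lists the duration of
    each visit to a state; the transition matrix counts moves between
    consecutive *differing* labels with the diagonal zeroed and rows
    normalized (all-zero rows mean the state was never left).
    """

    centers: np.ndarray
    labels: np.ndarray
    cost: float
    dwell_times_s: dict[int, list[float]] = field(default_factory=dict)
    transition_matrix: np.ndarray | None = None
    n_states_observed: int | None = None


def _l1_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return np.abs(X[:, None, :] - centers[None, :, :]).sum(axis=2)


def _kmedians_once(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    # k-means++-style seeding with L1 distances
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d = _l1_distances(X, centers[:1]).min(axis=1)
    for j in range(1, k):
        probs = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = X[rng.choice(n, p=probs)]
        d = np.minimum(d, np.abs(X - centers[j]).sum(axis=1))
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = _l1_distances(X, centers)
        new_labels = dist.argmin(axis=1)  # ties -> lowest center index
        for j in range(k):
            members = X[new_labels == j]
            if members.shape[0] == 0:
                # re-seed an empty cluster at the point farthest from its center
                far = dist.min(axis=1).argmax()
                centers[j] = X[far]
                new_labels[far] = j
            else:
                centers[j] = np.median(members, axis=0)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    cost = float(_l1_distances(X, centers)[np.arange(n), labels].sum())
    return centers, labels, cost


def cluster_states(
    stack: WindowedFCStack | np.ndarray,
    k: int = 7,
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = None,
) -> StateModel:
    """L1 k-means (k-medians) over vectorized windowed-FC matrices.

    Assignment minimizes the L1 distance to the centers; centers are
    updated as element-wise medians (the L1-optimal center).  The best of
    ``n_restarts`` runs by total L1 cost is kept, ties going to the
    earliest restart.  Labels in the returned model are 1-based.
    """
    X = stack.vectorized() if isinstance(stack, WindowedFCStack) else np.asarray(stack)
    if X.shape[0] < k:
        raise ValueError(f"only {X.shape[0]} windows for k={k} clusters")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers, labels, cost = _kmedians_once(X, k, rng)
        if best is None or cost < best[2]:
            best = (centers, labels, cost)
    centers, labels, cost = best
    return StateModel(centers=centers, labels=labels + 1, cost=cost)


def dwell_and_transitions(model: StateModel, step_s: float) -> StateModel:
    """Dwell times per visit and the between-state transition matrix.

    ``step_s`` is the time between consecutive windows.  Dwell time of a
    visit is its run length times ``step_s``.  Transitions count only
    changes of label; the diagonal is zero by construction and rows are
    normalized to probabilities (rows of never-left states stay zero).
    """
    labels = np.asarray(model.labels)
    if labels.size == 0:
        raise ValueError("state model has no labels")
    k = model.centers.shape[0]
    dwell: dict[int, list[float]] = {s: [] for s in range(1, k + 1)}
    counts = np.zeros((k, k))
    run_start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[run_start]:
            dwell[int(labels[run_start])].append((i - run_start) * step_s)
            if i < labels.size:
                counts[labels[run_start] - 1, labels[i] - 1] += 1
            run_start = i
    np.fill_diagonal(counts, 0.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    trans = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    model.dwell_times_s = {s: v for s, v in dwell.items() if v}
    model.transition_matrix = trans
    model.n_states_observed = int(np.unique(labels).size)
    return model


# --------------------------------------------------------------------- #
# estimator wrappers                                                    #
# --------------------------------------------------------------------- #


class QPPDetector(BaseEstimator):
    """Estimator wrapper around :func:`detect_qpp` / :func:`occurrence_rate`."""

    def __init__(
        self,
        window_s: float = 20.0,
        n_random_starts: int = 10,
        max_iter: int = 20,
        alpha: float = 0.05,
        n_surrogates: int = 100,
        random_state: int | None = None,
    ):
        self.window_s = window_s
        self.n_random_starts = n_random_starts
        self.max_iter = max_iter
        self.alpha = alpha
        self.n_surrogates = n_surrogates
        self.random_state = random_state

    def fit(self, X, y=None):
        rng = np.random.default_rng(self.random_state)
        self.template_ = detect_qpp(
            X,
            window_s=self.window_s,
            n_random_starts=self.n_random_starts,
            max_iter=self.max_iter,
            seed=rng,
        )
        self.occurrence_rate_ = occurrence_rate(
            self.template_,
            X,
            alpha=self.alpha,
            n_surrogates=self.n_surrogates,
            seed=rng,
        )
        self.corr_trace_ = self.template_.corr_trace
        return self


class FCStateClusterer(BaseEstimator):
    """Estimator wrapper around L1 k-means FC-state clustering.

    ``fit`` accepts a :class:`WindowedFCStack` or a matrix of vectorized
    windows; fitted attributes follow the sklearn clustering convention
    (``labels_`` here are 1-based to match the state-model convention).
    """

    def __init__(self, n_clusters: int = 7, n_restarts: int = 10,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        model = cluster_states(
            X, k=self.n_clusters, n_restarts=self.n_restarts, seed=self.random_state
        )
        self.state_model_ = model
        self.cluster_centers_ = model.centers
        self.labels_ = model.labels
        self.inertia_ = model.cost
        return self

    def predict(self, X) -> np.ndarray:
        Xv = X.vectorized() if isinstance(X, WindowedFCStack) else np.asarray(X)
        return _l1_distances(Xv, self.cluster_centers_).argmin(axis=1) + 1
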