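"""Seeded generators of resting-state-like fixtures.

Everything downstream — preprocessing, the autoencoder, the dynamical
analyses — is testable without any data download: band-limited, z-scored
ROI time series driven by noise-driven network dynamics on a synthetic
modular connectome, optionally with planted quasiperiodic events and
planted FC-state sequences whose ground truth is returned alongside the
signal.

The default generator is the firing-rate network model itself, so that
autoencoder recovery experiments are well-posed: when the data really are
produced by the latent model the encoder is asked to learn, latent-space
similarity to the generator state is a meaningful yardstick.  Events for
the pattern detector are pasted additively (not produced by the dynamics)
because the detection oracle needs exact ground-truth times.  No
hemodynamic convolution is applied: the model output is treated directly
as the fMRI-like signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bnm import FiringRateParams, WilsonCowanParams, simulate
from .connectome import StructuralNetwork, normalize_structural, synth_connectome
from .preprocess import DEFAULT_BAND_HZ, ROITimeSeries, bandpass, znormalize

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "gen_timeseries",
    "gen_dataset",
    "plant_qpp",
    "plant_states",
    "make_qpp_pattern",
]

_BURN_IN = 100


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic scan.

    Defaults emulate 66-region, TR 0.72 s resting-state data; ``M=20``
    with ``duration_s`` around 860 s (1,200 frames) is the fast test
    configuration.  ``kind`` selects the generator: the firing-rate or
    Wilson–Cowan network model, or spatially mixed AR(1) noise.

    ``noise_tau`` (frames) is the correlation time of the OU noise
    driving the network model.  The default of 8 frames (~5.8 s, the
    width of a canonical hemodynamic response) gives conditioned output
    whose frame-to-frame smoothness matches measured BOLD: the
    persistence one-step R^2 lands near the ~0.97 reported for real
    resting-state data.  Set 0 for a white drive.
    """

    M: int = 66
    tr_s: float = 0.72
    duration_s: float = 864.0
    kind: str = "fr_bnm"
    sigma: float = 0.1
    noise_tau: float = 8.0
    k: float = 0.9
    spatial_mix: float = 0.5
    n_modules: int = 6
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    target_lag1: float | None = None
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.tr_s))


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated scan."""

    connectome: StructuralNetwork | None = None
    state_trajectory: np.ndarray | None = None
    event_times: list[int] = field(default_factory=list)
    frame_labels: np.ndarray | None = None


def _lag1(data: np.ndarray) -> float:
    x = data - data.mean(axis=0)
    num = np.sum(x[1:] * x[:-1], axis=0)
    den = np.sum(x * x, axis=0)
    return float(np.mean(num / den))


def gen_timeseries(
    spec: SyntheticSpec,
    connectome: StructuralNetwork | None = None,
) -> tuple[ROITimeSeries, SyntheticTruth]:
    """Generate one conditioned synthetic scan plus its ground truth.

    The chosen generator is simulated on a (normalized) modular synthetic
    connectome past its initial transient, bandpass filtered to the
    resting-state band and two-axis z-normalized — the same conditioning
    applied to empirical ROI matrices.

    If ``target_lag1`` is set, the mean lag-one autocorrelation of the
    output is calibrated to within ±0.01 by blending in white measurement
    noise before filtering (which can only lower the autocorrelation; a
    target above the clean value raises).
    """
    rng = np.random.default_rng(spec.seed)
    if connectome is None:
        sn_raw = synth_connectome(M=spec.M, n_modules=spec.n_modules, seed=rng)
        sn = normalize_structural(sn_raw)
    else:
        sn = connectome if connectome.spectrally_normalized else normalize_structural(connectome)
    n = spec.n_frames

    if spec.kind == "fr_bnm":
        raw_ts = simulate(
            "firing_rate", sn,
            FiringRateParams(k=spec.k, sigma=spec.sigma, noise_tau=spec.noise_tau),
            n_steps=n, seed=rng, tr_s=spec.tr_s, burn_in=_BURN_IN,
        )
        raw = raw_ts.data
        trajectory = raw.copy()
    elif spec.kind == "wc_bnm":
        raw_ts = simulate(
            "wilson_cowan", sn,
            WilsonCowanParams(k_e=spec.k, k_i=spec.k, sigma=spec.sigma,
                              noise_tau=spec.noise_tau),
            n_steps=n, seed=rng, tr_s=spec.tr_s, burn_in=_BURN_IN,
        )
        raw = raw_ts.data
        trajectory = raw.copy()
    elif spec.kind == "ar_noise":
        raw = _ar_noise(n, spec.M, rho=0.9, mix=spec.spatial_mix, rng=rng)
        trajectory = None
    else:
        raise ValueError(f"unknown generator kind {spec.kind!r}")

    def condition(x: np.ndarray) -> ROITimeSeries:
        ts = ROITimeSeries(data=x, tr_s=spec.tr_s, roi_labels=list(sn.roi_labels),
                           provenance=[f"synth[{spec.kind}]"])
        ts = bandpass(ts, *spec.band_hz)
        return znormalize(ts)

    if spec.target_lag1 is None:
        out = condition(raw)
    else:
        out = _calibrate_lag1(raw, condition, spec.target_lag1, rng)

    truth = SyntheticTruth(connectome=sn, state_trajectory=trajectory)
    return out, truth


def _ar_noise(n: int, M: int, rho: float, mix: float,
              rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise, optionally spatially mixed.

    ``mix`` interpolates between independent regions (0, the clean
    planted-pattern oracle background) and strongly shared fluctuations
    (1, a crude stand-in for global signal and network covariance).
    """
    innov = rng.standard_normal((n + _BURN_IN, M))
    x = np.empty_like(innov)
    x[0] = innov[0]
    for t in range(1, innov.shape[0]):
        x[t] = rho * x[t - 1] + np.sqrt(1 - rho ** 2) * innov[t]
    if mix > 0:
        mixer = mix * rng.standard_normal((M, M)) / np.sqrt(M) + np.eye(M)
        x = x @ mixer.T
    return x[_BURN_IN:]


def _calibrate_lag1(raw, condition, target, rng, tol=0.01, max_iter=40):
    """Bisect a white-noise blend weight until the output lag-1 matches target."""
    noise = rng.standard_normal(raw.shape)

    def measure(w: float) -> float:
        scale = raw.std()
        return _lag1(condition((1 - w) * raw + w * scale * noise).data)

    lo, hi = 0.0, 1.0
    r_lo = measure(lo)
    if r_lo < target - tol:
        raise ValueError(
            f"target lag-1 autocorrelation {target} unattainable: clean signal "
            f"reaches only {r_lo:.3f}"
        )
    if abs(r_lo - target) <= tol:
        return condition(raw)
    r_hi = measure(hi)
    if r_hi > target + tol:
        raise ValueError(
            f"target lag-1 autocorrelation {target} unattainable: even pure "
            f"noise yields {r_hi:.3f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = measure(mid)
        if abs(r - target) <= tol:
            scale = raw.std()
            return condition((1 - mid) * raw + mid * scale * noise)
        if r > target:
            lo = mid
        else:
            hi = mid
    raise ValueError("lag-1 calibration did not converge")


def gen_dataset(
    spec: SyntheticSpec, n_scans: int, seed: int | None = None
) -> tuple[list[ROITimeSeries], SyntheticTruth]:
    """Generate several scans sharing one connectome (independent noise).

    Scan seeds are spawned from ``seed`` so the dataset is reproducible as
    a whole; the shared connectome mirrors a cohort scanned on a common
    atlas.
    """
    ss = np.random.SeedSequence(seed)
    conn_rng = np.random.default_rng(ss.spawn(1)[0])
    sn = normalize_structural(
        synth_connectome(M=spec.M, n_modules=spec.n_modules, seed=conn_rng)
    )
    scans = []
    truth = SyntheticTruth(connectome=sn)
    for child in ss.spawn(n_scans):
        sub = SyntheticSpec(**{**spec.__dict__, "seed": None})
        sub.seed = child.generate_state(1)[0] % (2 ** 31)
        ts, _ = gen_timeseries(sub, connectome=sn)
        scans.append(ts)
    return scans, truth


def make_qpp_pattern(
    W: int, M: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """A smooth W x M test pattern with unit variance overall.

    A Hann-tapered one-cycle transient with random per-region phases and
    amplitudes.  The taper spreads the spectrum (so the pattern is
    distinguishable from any single narrowband background oscillation)
    while the smooth fundamental keeps template recovery robust to the
    one-or-two-frame jitter of correlation peaks in noise.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(W) / W
    env = np.hanning(W)[:, None]
    phase = rng.uniform(0, 2 * np.pi, size=M)
    amp = rng.uniform(0.5, 1.5, size=M)
    pat = env * amp * np.sin(2 * np.pi * t[:, None] + phase)
    return pat / pat.std()


def plant_qpp(
    ts: ROITimeSeries,
    template: np.ndarray,
    rate_per_min: float,
    amplitude: float = 1.0,
    min_gap_frames: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[ROITimeSeries, list[int]]:
    """Paste a repeating pattern into a scan at Poisson-thinned times.

    Candidate onsets form a Poisson process with the requested rate
    (proposal probability inflated to cancel the dead time imposed by
    ``min_gap_frames``, which defaults to the template length).
    ``amplitude`` is the event-to-background standard-deviation ratio
    *after* the final re-z-normalization: the paste scale is
    pre-compensated for the variance the events themselves add, so
    ``amplitude=1`` really is SNR 1 in the returned scan.  Returns the
    modified scan and the exact onset list — the detection oracle.
    """
    template = np.asarray(template, dtype=float)
    W, M = template.shape
    T = ts.n_frames
    if M != ts.n_rois:
        raise ValueError("template and scan have different numbers of regions")
    if W > T // 3:
        raise ValueError("template too long relative to the scan")
    if rate_per_min < 0:
        raise ValueError("rate must be nonnegative")
    if min_gap_frames is None:
        min_gap_frames = W
    rng = np.random.default_rng(seed)

    frames_per_event = 60.0 / (ts.tr_s * rate_per_min) if rate_per_min > 0 else np.inf
    if rate_per_min > 0 and min_gap_frames >= 0.8 * frames_per_event:
        raise ValueError(
            "infeasible rate/gap combination: the minimum gap leaves no room "
            "for the requested event rate"
        )

    events: list[int] = []
    if rate_per_min > 0:
        a = rate_per_min * ts.tr_s / 60.0  # desired accepted events per frame
        # dead-time correction: each accepted event blocks min_gap frames,
        # so the proposal rate must be inflated to realize the target rate
        p_frame = a / (1.0 - a * min_gap_frames)
        t = 0
        last = -min_gap_frames - 1
        while t <= T - W:
            if t - last > min_gap_frames and rng.random() < p_frame:
                events.append(t)
                last = t
            t += 1

    data = ts.data.copy()
    # occupied-frame fraction; compensate the variance the events add so the
    # requested amplitude survives the final re-normalization
    f = len(events) * W / T
    if f * amplitude ** 2 >= 1.0:
        raise ValueError("amplitude/rate too large: events would dominate the scan")
    scale = amplitude * data.std() / np.sqrt(1.0 - f * amplitude ** 2)
    for t0 in events:
        data[t0 : t0 + W] += scale * template
    if amplitude != 0 and events:
        # per-region re-standardization only: a frame-axis pass would act as
        # dynamic gain control and squash exactly the coherent event frames
        data = (data - data.mean(axis=0)) / data.std(axis=0)
    out = ROITimeSeries(data=data, tr_s=ts.tr_s, roi_labels=list(ts.roi_labels),
                        provenance=list(ts.provenance) + ["plant_qpp"])
    return out, events


def plant_states(
    M: int,
    k: int,
    n_windows: int,
    window_frames: int,
    dwell_mean_windows: float = 2.0,
    separation: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[ROITimeSeries, np.ndarray]:
    """Piecewise-stationary Gaussian series with k planted covariance regimes.

    Each state has a distinct random correlation structure (a rank-2
    factor model ``B @ B.T + I``, scaled by ``separation``); state
    durations are geometric with the given mean in windows.  Returns the
    series and the per-frame state labels (1-based).
    """
    if k < 1:
        raise ValueError("need at least one state")
    if k > n_windows:
        raise ValueError("more states than windows")
    rng = np.random.default_rng(seed)

    chols = []
    for _ in range(k):
        B = rng.standard_normal((M, 2)) * separation
        cov = B @ B.T + np.eye(M)
        chols.append(np.linalg.cholesky(cov))

    # geometric dwell in windows, mean dwell_mean_windows
    p = min(1.0, 1.0 / dwell_mean_windows)
    window_states = []
    state = int(rng.integers(k))
    while len(window_states) < n_windows:
        window_states.append(state)
        if rng.random() < p and k > 1:
            nxt = int(rng.integers(k - 1))
            state = nxt if nxt < state else nxt + 1
    window_states = np.array(window_states[:n_windows])

    T = n_windows * window_frames
    data = np.empty((T, M))
    labels = np.empty(T, dtype=int)
    for w, s in enumerate(window_states):
        sl = slice(w * window_frames, (w + 1) * window_frames)
        data[sl] = rng.standard_normal((window_frames, M)) @ chols[s].T
        labels[sl] = s + 1
    ts = ROITimeSeries(data=data, tr_s=0.72, provenance=["plant_states"])
    return ts, labels
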