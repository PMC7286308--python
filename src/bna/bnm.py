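"""Traditional brain network model simulators.

Two neural-mass models on a structural connectome, Euler-integrated at the
frame rate of the measurement with additive Gaussian state noise:

* firing-rate model — linear consensus dynamics ``x' = -x + k * SN @ x``;
* Wilson–Cowan model — coupled excitatory/inhibitory currents per region,
  each relaxing toward a sigmoidal drive that mixes local E/I recurrence, a
  constant input, and network input ``sum_j w_ij * (E_j + I_j)``.

The integration step defaults to one frame (one repetition time): these
models are meant to be synchronized with the measurement grid, which is
also why oscillator models that need much finer steps are not included.
Noise enters after the deterministic Euler increment, scaled by
``sigma * sqrt(dt)`` (Euler–Maruyama convention, so refining ``dt`` keeps
the diffusion consistent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.special

from .connectome import CouplingMatrix, StructuralNetwork, graph_laplacian
from .preprocess import ROITimeSeries

__all__ = [
    "FiringRateParams",
    "WilsonCowanParams",
    "sigmoid",
    "fr_step",
    "wc_step",
    "simulate",
]


@dataclass
class FiringRateParams:
    """Firing-rate model constants.

    ``k`` is the global coupling, ``sigma`` the state-noise standard
    deviation per step, ``dt`` the Euler step in frames.  ``noise_tau``
    (frames) optionally colors the noise drive as an Ornstein–Uhlenbeck
    process with that correlation time; 0 keeps the drive white, the
    model's plain form.  A hemodynamics-like value (~8 frames at TR
    0.72 s) produces signals whose frame-to-frame smoothness matches
    measured BOLD.
    """

    k: float = 0.9
    sigma: float = 0.1
    dt: float = 1.0
    noise_tau: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.k < 1.0):
            raise ValueError("k must lie in (0, 1) for stable dynamics")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not (0.0 < self.dt <= 1.0):
            raise ValueError("dt must lie in (0, 1] frames")
        if self.noise_tau < 0:
            raise ValueError("noise_tau must be nonnegative")


@dataclass
class WilsonCowanParams:
    """Wilson–Cowan constants.

    ``k_e`` / ``k_i`` are the constant drives inside the excitatory and
    inhibitory sigmoids (both 0.9 by default, matching the firing-rate
    coupling constant).  The local coupling constants default to the
    classic planar Wilson–Cowan values ``c_ee=16, c_ei=12, c_ie=15,
    c_ii=3`` with gain ``alpha=1``; they are deliberately configurable
    because in the autoencoder setting they may also be learned.
    """

    k_e: float = 0.9
    k_i: float = 0.9
    alpha: float = 1.0
    c_ee: float = 16.0
    c_ei: float = 12.0
    c_ie: float = 15.0
    c_ii: float = 3.0
    sigma: float = 0.1
    dt: float = 1.0
    noise_tau: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("c_ee", "c_ei", "c_ie", "c_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not (0.0 < self.dt <= 1.0):
            raise ValueError("dt must lie in (0, 1] frames")
        if self.noise_tau < 0:
            raise ValueError("noise_tau must be nonnegative")


def sigmoid(x):
    """Logistic function ``1 / (1 + exp(-x))``, numerically stable."""
    return scipy.special.expit(x)


def fr_step(
    x: np.ndarray,
    A: CouplingMatrix | np.ndarray,
    p: FiringRateParams,
    noise_draw: np.ndarray | None = None,
) -> np.ndarray:
    """One Euler step of the firing-rate model.

    ``x(n+1) = x(n) + dt * A @ x(n) + sigma * sqrt(dt) * noise_draw`` where
    ``A = k * SN - I`` and ``noise_draw`` is a standard-normal vector.
    """
    Amat = A.A if isinstance(A, CouplingMatrix) else np.asarray(A)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != Amat.shape[0]:
        raise ValueError(
            f"state dimension {x.shape[-1]} does not match coupling matrix "
            f"size {Amat.shape[0]}"
        )
    out = x + p.dt * (x @ Amat.T)
    if noise_draw is not None and p.sigma > 0:
        out = out + p.sigma * np.sqrt(p.dt) * np.asarray(noise_draw)
    return out


def wc_step(
    state: tuple[np.ndarray, np.ndarray],
    sn: StructuralNetwork,
    p: WilsonCowanParams,
    noise_draw: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step of the Wilson–Cowan model.

    The network input ``sum_j w_ij * (E_j + I_j)`` enters both sigmoids;
    excitatory and inhibitory populations share the structural weights.
    Returns the updated ``(E, I)`` pair.
    """
    E, I = (np.asarray(s, dtype=float) for s in state)
    W = sn.weights
    if E.shape != I.shape or E.shape[-1] != W.shape[0]:
        raise ValueError("state dimensions do not match connectome size")
    net = (E + I) @ W.T
    aE = p.c_ee * E - p.c_ei * I + p.k_e + net
    aI = p.c_ie * E - p.c_ii * I + p.k_i + net
    E_next = E + p.dt * (-E + p.alpha * sigmoid(aE))
    I_next = I + p.dt * (-I + p.alpha * sigmoid(aI))
    if noise_draw is not None and p.sigma > 0:
        s = p.sigma * np.sqrt(p.dt)
        E_next = E_next + s * np.asarray(noise_draw[0])
        I_next = I_next + s * np.asarray(noise_draw[1])
    return E_next, I_next


def simulate(
    kind: str,
    sn: StructuralNetwork,
    params: FiringRateParams | WilsonCowanParams | None = None,
    n_steps: int = 1000,
    x0: np.ndarray | tuple[np.ndarray, np.ndarray] | None = None,
    seed: int | np.random.Generator | None = None,
    tr_s: float = 0.72,
    burn_in: int = 0,
) -> ROITimeSeries:
    """Simulate a neural-mass model on the connectome and return a T x M series.

    Firing-rate output is the state ``x`` itself; Wilson–Cowan output is the
    excitatory current ``E`` (taken as the fMRI-like signal, since it
    dominates metabolically).  Initial conditions default to standard-normal
    draws; ``burn_in`` extra initial steps are simulated and discarded so the
    retained segment is past the initial transient.  Reproducible by seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    rng = np.random.default_rng(seed)
    M = sn.n_rois
    total = n_steps + burn_in

    def make_noise_source(p):
        """Standard-normal draws, optionally OU-colored with unit variance."""
        if p.noise_tau <= 0:
            return lambda: rng.standard_normal(M)
        a = np.exp(-p.dt / p.noise_tau)
        state = {"n": rng.standard_normal(M)}

        def draw():
            out = state["n"]
            state["n"] = a * out + np.sqrt(1 - a ** 2) * rng.standard_normal(M)
            return out

        return draw

    if kind == "firing_rate":
        p = params or FiringRateParams()
        if not isinstance(p, FiringRateParams):
            raise TypeError("firing_rate simulation needs FiringRateParams")
        if not sn.spectrally_normalized:
            raise ValueError("connectome must be spectrally normalized")
        A = graph_laplacian(sn, p.k)
        x = rng.standard_normal(M) if x0 is None else np.asarray(x0, dtype=float)
        noise = make_noise_source(p)
        out = np.empty((total, M))
        for t in range(total):
            draw = noise() if p.sigma > 0 else None
            x = fr_step(x, A, p, draw)
            out[t] = x
    elif kind == "wilson_cowan":
        p = params or WilsonCowanParams()
        if not isinstance(p, WilsonCowanParams):
            raise TypeError("wilson_cowan simulation needs WilsonCowanParams")
        if x0 is None:
            E = rng.standard_normal(M)
            I = rng.standard_normal(M)
        else:
            E, I = (np.asarray(s, dtype=float) for s in x0)
        noise_e, noise_i = make_noise_source(p), make_noise_source(p)
        out = np.empty((total, M))
        for t in range(total):
            draw = (noise_e(), noise_i()) if p.sigma > 0 else None
            E, I = wc_step((E, I), sn, p, draw)
            out[t] = E
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    return ROITimeSeries(
        data=out[burn_in:],
        tr_s=tr_s,
        roi_labels=list(sn.roi_labels),
        provenance=[f"simulate[{kind}]"],
    )
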