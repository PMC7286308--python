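"""Structural connectomes: validation, normalization, coupling operators, synthetic graphs.

A structural network holds the fiber strengths ``w_ij`` between cortical
regions.  For whole-brain network dynamics the matrix is conditioned so that
the linear coupling operator ``A = k * SN - I`` (a graph-Laplacian-like
"consensus" operator) has a strictly negative spectrum for ``0 < k < 1``,
which guarantees that network propagation decays instead of blowing up.
That requires the connectome to be symmetric with spectral radius one, so
:func:`normalize_structural` symmetrizes and rescales by the largest-magnitude
eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "StructuralNetwork",
    "CouplingMatrix",
    "normalize_structural",
    "graph_laplacian",
    "synth_connectome",
]


def _default_labels(m: int) -> list[str]:
    return [f"ROI_{i:03d}" for i in range(m)]


@dataclass
class StructuralNetwork:
    """M x M nonnegative fiber-strength matrix with normalization state.

    ``weights[i, j]`` is the strength of the projection from region ``j``
    into region ``i``.  The diagonal is zero: self-decay is carried by the
    ``-I`` term of the coupling operator, so self-loops here would be
    double-counted.
    """

    weights: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    area_normalized: bool = False
    spectrally_normalized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome contains non-finite entries")
        if np.any(w < 0):
            raise ValueError("connectome contains negative entries")
        self.weights = w
        if not self.roi_labels:
            self.roi_labels = _default_labels(w.shape[0])
        if len(self.roi_labels) != w.shape[0]:
            raise ValueError("roi_labels length does not match matrix size")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    def spectral_radius(self) -> float:
        if np.allclose(self.weights, self.weights.T):
            eig = scipy.linalg.eigvalsh(self.weights)
        else:
            eig = scipy.linalg.eigvals(self.weights)
        return float(np.max(np.abs(eig)))


@dataclass
class CouplingMatrix:
    """Linear coupling operator ``A = k * SN - I`` with its coupling constant."""

    A: np.ndarray
    k: float

    @property
    def n_rois(self) -> int:
        return self.A.shape[0]


def normalize_structural(
    sn: StructuralNetwork, areas: np.ndarray | None = None
) -> StructuralNetwork:
    """Condition a raw fiber-count matrix for stable network dynamics.

    Steps, in order: divide each row by the surface area of the receiving
    region (when ``areas`` is given), zero the diagonal, symmetrize as
    ``(W + W.T) / 2`` (streamline counts are undirected; symmetry is what
    makes the eigenvalue-negativity argument for the coupling operator go
    through), and finally divide by the largest-magnitude eigenvalue so the
    spectral radius is exactly one.

    Parameters
    ----------
    sn : StructuralNetwork
        Raw nonnegative square matrix.
    areas : array of shape (M,), optional
        Strictly positive surface areas of the receiving regions.

    Returns
    -------
    StructuralNetwork
        New network with ``spectrally_normalized=True``.
    """
    w = np.array(sn.weights, dtype=float, copy=True)
    if areas is not None:
        areas = np.asarray(areas, dtype=float)
        if areas.shape != (sn.n_rois,):
            raise ValueError("areas must have one entry per ROI")
        if np.any(areas <= 0):
            raise ValueError("areas must be strictly positive")
        w /= areas[:, None]
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    radius = np.max(np.abs(scipy.linalg.eigvalsh(w)))
    if radius <= 0:
        raise ValueError("zero matrix: spectral radius is 0, cannot normalize")
    w /= radius
    return StructuralNetwork(
        weights=w,
        roi_labels=list(sn.roi_labels),
        area_normalized=areas is not None,
        spectrally_normalized=True,
    )


def graph_laplacian(sn: StructuralNetwork, k: float = 0.9) -> CouplingMatrix:
    """Build the consensus coupling operator ``A = k * SN - I``.

    For a symmetric, spectrally normalized connectome and ``0 < k < 1``
    every eigenvalue of ``A`` lies in ``[-(1+k), k-1]`` and is therefore
    strictly negative, so the noise-free linear dynamics ``x' = A x`` decay.

    The default ``k = 0.9`` is used throughout: nearby values behave almost
    identically because the encoder absorbs the rescaling, so the constant
    only needs to sit safely inside the stable range.
    """
    if not sn.spectrally_normalized:
        raise ValueError("connectome must be spectrally normalized first")
    if not (0.0 < k < 1.0):
        raise ValueError(f"global coupling k must lie in (0, 1), got {k}")
    A = k * sn.weights - np.eye(sn.n_rois)
    return CouplingMatrix(A=A, k=float(k))


def synth_connectome(
    M: int = 66,
    n_modules: int = 6,
    intra_density: float = 0.8,
    inter_density: float = 0.15,
    interhemispheric_fraction: float = 0.2,
    seed: int | np.random.Generator | None = None,
    weight_sigma: float = 0.5,
) -> StructuralNetwork:
    """Generate a random modular, bi-hemispheric connectome.

    The M regions are split into two "hemispheres" of ``n_modules / 2``
    contiguous modules each.  Within-module edges are dense, between-module
    edges within a hemisphere are sparser, and inter-hemispheric edge
    probability is further thinned by ``interhemispheric_fraction`` — the
    hallmark of tractography-derived connectomes, where cross-hemisphere
    fibers are systematically under-detected.  Edge weights are lognormal.

    Returns a symmetric, nonnegative, zero-diagonal matrix; reproducible
    from ``seed``.
    """
    if M < 2:
        raise ValueError("need at least two regions")
    if n_modules < 1 or M < n_modules:
        raise ValueError("need M >= n_modules >= 1")
    for name, d in [("intra_density", intra_density), ("inter_density", inter_density)]:
        if not (0.0 < d <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {d}")
    if not (0.0 <= interhemispheric_fraction <= 1.0):
        raise ValueError("interhemispheric_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    module = np.floor(np.arange(M) * n_modules / M).astype(int)
    half = M // 2
    hemi = (np.arange(M) >= half).astype(int)

    w = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            if module[i] == module[j]:
                p = intra_density
            elif hemi[i] == hemi[j]:
                p = inter_density
            else:
                p = inter_density * interhemispheric_fraction
            if rng.random() < p:
                w[i, j] = w[j, i] = rng.lognormal(mean=0.0, sigma=weight_sigma)
    # avoid isolated regions, which would carry no network signal at all
    for i in range(M):
        if not np.any(w[i] > 0):
            peers = np.flatnonzero((module == module[i]) & (np.arange(M) != i))
            j = int(rng.choice(peers)) if peers.size else int((i + 1) % M)
            w[i, j] = w[j, i] = rng.lognormal(mean=0.0, sigma=weight_sigma)

    labels = [
        f"{'L' if h == 0 else 'R'}_m{m}_{i:03d}"
        for i, (h, m) in enumerate(zip(hemi, module))
    ]
    return StructuralNetwork(weights=w, roi_labels=labels)


def module_partition(M: int, n_modules: int) -> np.ndarray:
    """Module assignment used by :func:`synth_connectome` (ground truth)."""
    return np.floor(np.arange(M) * n_modules / M).astype(int)
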