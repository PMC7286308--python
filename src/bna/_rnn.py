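"""Numpy stacked-LSTM engine with manual backpropagation.

This is the numerical core behind the autoencoder: a stack of LSTM layers,
Gaussian output heads (per-frame latent mean and standard deviation with a
reparameterized sample), and reverse-mode gradients written out by hand,
optimized with Adam.  The output heads carry a linear skip path from the
two most recent input frames, so the encoder starts from a sensible
near-identity latent map and the recurrent stack learns the temporal
correction on top.

Everything is float64 and deterministic given the generators passed in.
Gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import scipy.special

Array = np.ndarray

__all__ = ["LSTMCore", "softplus", "inv_softplus"]


def softplus(x: Array) -> Array:
    return np.logaddexp(0.0, x)


def inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


def _expit(x: Array) -> Array:
    return scipy.special.expit(x)


class LSTMCore:
    """Stacked LSTM encoder with Gaussian latent heads.

    Parameters are plain float64 arrays in ``self.params``; the class holds
    no external-framework state.  ``bnm_forward`` / ``bnm_vjp`` supplied to
    :meth:`loss_and_grads` map sampled latents to predicted frames and pull
    prediction gradients back, so the same engine serves any latent model
    with a differentiable one-step integrator.
    """

    def __init__(
        self,
        n_inputs: int,
        latent_per_roi: int,
        units: int = 64,
        n_layers: int = 2,
        dropout: float = 0.0,
        std_floor: float = 1e-4,
        init_std: float = 0.01,
        v0_init: Array | None = None,
        rng: np.random.Generator | None = None,
    ):
        if n_layers < 1:
            raise ValueError("need at least one recurrent layer")
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        rng = rng or np.random.default_rng()
        self.M = n_inputs
        self.S = latent_per_roi
        self.D = n_inputs * latent_per_roi
        self.H = units
        self.n_layers = n_layers
        self.dropout = dropout
        self.std_floor = std_floor

        p: dict[str, Array] = {}
        scale = 1.0 / np.sqrt(units)
        for l in range(n_layers):
            d_in = self.M if l == 0 else units
            p[f"Wx{l}"] = rng.uniform(-scale, scale, size=(d_in, 4 * units))
            p[f"Wh{l}"] = rng.uniform(-scale, scale, size=(units, 4 * units))
            b = np.zeros(4 * units)
            b[units:2 * units] = 1.0  # forget-gate bias: remember by default
            p[f"b{l}"] = b
        p["Wm"] = np.zeros((units, self.D))
        p["V0"] = np.zeros((self.M, self.D)) if v0_init is None else np.array(v0_init, dtype=float)
        p["V1"] = np.zeros((self.M, self.D))
        p["bm"] = np.zeros(self.D)
        p["Ws"] = np.zeros((units, self.D))
        p["bs"] = np.full(self.D, inv_softplus(init_std))
        self.params = p
        self._adam: dict[str, tuple[Array, Array]] | None = None
        self._adam_t = 0

    # ------------------------------------------------------------------ #
    # forward passes                                                     #
    # ------------------------------------------------------------------ #

    def zero_state(self, batch: int) -> list[tuple[Array, Array]]:
        return [
            (np.zeros((batch, self.H)), np.zeros((batch, self.H)))
            for _ in range(self.n_layers)
        ]

    def _run_layers(
        self,
        X: Array,
        state: list[tuple[Array, Array]] | None,
        training: bool,
        rng: np.random.Generator | None,
    ):
        """Run the LSTM stack over ``X`` of shape (B, T, M).

        Returns per-layer caches (gates, cells, hidden traces, inputs,
        dropout masks) and the final recurrent state.
        """
        B, T, _ = X.shape
        H = self.H
        state = state or self.zero_state(B)
        caches = []
        inp = X
        new_state = []
        for l in range(self.n_layers):
            Wx, Wh, b = self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"b{l}"]
            Zx = inp.reshape(B * T, -1) @ Wx
            Zx = Zx.reshape(B, T, 4 * H) + b
            h, c = state[l]
            h0, c0 = h, c
            Ig = np.empty((B, T, H)); Fg = np.empty((B, T, H))
            Og = np.empty((B, T, H)); Gg = np.empty((B, T, H))
            C = np.empty((B, T, H)); Hs = np.empty((B, T, H))
            for t in range(T):
                z = Zx[:, t] + h @ Wh
                i = _expit(z[:, :H])
                f = _expit(z[:, H:2 * H])
                o = _expit(z[:, 2 * H:3 * H])
                g = np.tanh(z[:, 3 * H:])
                c = f * c + i * g
                h = o * np.tanh(c)
                Ig[:, t] = i; Fg[:, t] = f; Og[:, t] = o; Gg[:, t] = g
                C[:, t] = c; Hs[:, t] = h
            new_state.append((h, c))
            out = Hs
            mask = None
            if training and self.dropout > 0 and l < self.n_layers - 1:
                keep = 1.0 - self.dropout
                mask = (rng.random(out.shape) < keep) / keep
                out = out * mask
            caches.append(
                dict(inp=inp, Ig=Ig, Fg=Fg, Og=Og, Gg=Gg, C=C, Hs=Hs,
                     h0=h0, c0=c0, mask=mask)
            )
            inp = out
        return caches, new_state

    def _heads(self, Htop: Array, Xp: Array, Xprev: Array):
        """Latent mean/std at selected positions.

        ``Htop``: (B, P, H) top hidden states; ``Xp`` / ``Xprev``: the input
        frames at the same positions and one frame earlier (skip paths).
        """
        p = self.params
        mean = Htop @ p["Wm"] + Xp @ p["V0"] + Xprev @ p["V1"] + p["bm"]
        s = Htop @ p["Ws"] + p["bs"]
        std = softplus(s) + self.std_floor
        return mean, std, s

    def encode(
        self,
        X: Array,
        state: list[tuple[Array, Array]] | None = None,
    ):
        """Latent distribution for every frame of ``X`` (B, T, M).

        Returns ``(mean, std, final_state, h_top)`` with mean/std of shape
        (B, T, D).  The lag-one skip frame for the first position is the
        first frame itself when no true predecessor exists.
        """
        caches, new_state = self._run_layers(X, state, training=False, rng=None)
        Htop = caches[-1]["Hs"]
        Xprev = np.concatenate([X[:, :1], X[:, :-1]], axis=1)
        mean, std, _ = self._heads(Htop, X, Xprev)
        return mean, std, new_state, Htop

    def step(self, x_t: Array, state: list[tuple[Array, Array]], x_prev: Array):
        """Advance the stack one frame; returns latent mean/std and new state."""
        H = self.H
        inp = x_t
        new_state = []
        for l in range(self.n_layers):
            Wx, Wh, b = self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"b{l}"]
            h, c = state[l]
            z = inp @ Wx + h @ Wh + b
            i = _expit(z[:, :H]); f = _expit(z[:, H:2 * H])
            o = _expit(z[:, 2 * H:3 * H]); g = np.tanh(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            new_state.append((h, c))
            inp = h
        mean, std, _ = self._heads(inp[:, None], x_t[:, None], x_prev[:, None])
        return mean[:, 0], std[:, 0], new_state

    # ------------------------------------------------------------------ #
    # training                                                           #
    # ------------------------------------------------------------------ #

    def loss_and_grads(
        self,
        X: Array,
        positions: Array,
        rng: np.random.Generator,
        bnm_forward: Callable[[Array], tuple[Array, object]],
        bnm_vjp: Callable[[object, Array], Array],
        kl_weight: float = 0.0,
    ):
        """Mean-squared next-frame error and gradients on a (B, T, M) batch.

        Latents are sampled (reparameterized) at every position ``p`` in
        ``positions`` and integrated one model step to predict frame
        ``p + 1``; the loss pools the squared error over positions, batch
        and regions.  Positions must satisfy ``1 <= p <= T - 2`` so both
        the lag-one skip frame and the target frame exist.
        """
        B, T, M = X.shape
        P = np.asarray(positions)
        if P.min() < 1 or P.max() > T - 2:
            raise ValueError("positions must leave room for a predecessor and a target")
        p = self.params
        caches, _ = self._run_layers(X, None, training=True, rng=rng)
        Htop = caches[-1]["Hs"][:, P]
        Xp = X[:, P]
        Xprev = X[:, P - 1]
        mean, std, s = self._heads(Htop, Xp, Xprev)
        eps = rng.standard_normal(mean.shape)
        z = mean + std * eps
        pred, bnm_cache = bnm_forward(z)
        target = X[:, P + 1]
        res = pred - target
        loss = float(np.mean(res ** 2))

        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dpred = (2.0 / res.size) * res
        dz = bnm_vjp(bnm_cache, dpred)
        dmean = dz.copy()
        dstd = dz * eps
        if kl_weight > 0.0:
            n = mean.size
            loss += kl_weight * float(
                np.mean(0.5 * (mean ** 2 + std ** 2 - 2.0 * np.log(std) - 1.0))
            )
            dmean += kl_weight * mean / n
            dstd += kl_weight * (std - 1.0 / std) / n
        ds = dstd * _expit(s)

        BP = Htop.reshape(-1, self.H)
        grads["Wm"] = BP.T @ dmean.reshape(-1, self.D)
        grads["Ws"] = BP.T @ ds.reshape(-1, self.D)
        grads["V0"] = Xp.reshape(-1, M).T @ dmean.reshape(-1, self.D)
        grads["V1"] = Xprev.reshape(-1, M).T @ dmean.reshape(-1, self.D)
        grads["bm"] = dmean.sum(axis=(0, 1))
        grads["bs"] = ds.sum(axis=(0, 1))

        dHtop_sel = dmean @ p["Wm"].T + ds @ p["Ws"].T
        dH = np.zeros((B, T, self.H))
        dH[:, P] = dHtop_sel

        for l in reversed(range(self.n_layers)):
            cache = caches[l]
            Wx, Wh = p[f"Wx{l}"], p[f"Wh{l}"]
            Ig, Fg, Og, Gg = cache["Ig"], cache["Fg"], cache["Og"], cache["Gg"]
            C, h0, c0 = cache["C"], cache["h0"], cache["c0"]
            dZ = np.empty((B, T, 4 * self.H))
            gWh = np.zeros_like(Wh)
            gb = np.zeros(4 * self.H)
            dh_next = np.zeros((B, self.H))
            dc = np.zeros((B, self.H))
            Hs = cache["Hs"]
            for t in reversed(range(T)):
                dh = dH[:, t] + dh_next
                tc = np.tanh(C[:, t])
                i, f, o, g = Ig[:, t], Fg[:, t], Og[:, t], Gg[:, t]
                dc = dc + dh * o * (1.0 - tc ** 2)
                c_prev = C[:, t - 1] if t > 0 else c0
                h_prev = Hs[:, t - 1] if t > 0 else h0
                di = dc * g
                df = dc * c_prev
                do = dh * tc
                dg = dc * i
                dz_t = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        do * o * (1.0 - o),
                        dg * (1.0 - g ** 2),
                    ],
                    axis=1,
                )
                dZ[:, t] = dz_t
                gWh += h_prev.T @ dz_t
                gb += dz_t.sum(axis=0)
                dh_next = dz_t @ Wh.T
                dc = dc * f
            inp = cache["inp"]
            flat_in = inp.reshape(B * T, -1)
            flat_dZ = dZ.reshape(B * T, 4 * self.H)
            grads[f"Wx{l}"] = flat_in.T @ flat_dZ
            grads[f"Wh{l}"] = gWh
            grads[f"b{l}"] = gb
            if l > 0:
                d_inp = (flat_dZ @ Wx.T).reshape(B, T, self.H)
                mask = caches[l - 1]["mask"]
                if mask is not None:
                    d_inp = d_inp * mask
                dH = d_inp
        return loss, grads

    def adam_step(
        self,
        grads: dict[str, Array],
        lr: float,
        clip: float | None = None,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        """One Adam update, with optional global-norm gradient clipping."""
        if clip is not None and clip > 0:
            norm = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads.values()))
            if norm > clip:
                scale = clip / norm
                grads = {k: g * scale for k, g in grads.items()}
        if self._adam is None:
            self._adam = {
                k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()
            }
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m, v = self._adam[k]
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g ** 2
            self._adam[k] = (m, v)
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
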