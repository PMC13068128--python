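"""A small, dependency-free LSTM sequence classifier engine.

Implements stacked (optionally bidirectional) LSTM layers with a linear
softmax head, backpropagation through time, inter-layer dropout and an Adam
optimizer, all in numpy.  Sized for whole-night feature sequences (hundreds
of 30 s epochs, a dozen features) on a single CPU; everything is a
deterministic function of the parameters, inputs and the seeded generator.

Shapes: inputs are (T, B, D) time-major batches; padded steps (sequences
shorter than T) are excluded through the loss mask, so recurrent state past
a sequence end never influences a gradient.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["SequenceNet", "Adam"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _LSTMLayer:
    """One direction of one LSTM layer.  Gate packing order: i, f, g, o."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.d_in = d_in
        self.hidden = hidden
        self.Wx = _glorot(rng, d_in, 4 * hidden)
        self.Wh = _glorot(rng, hidden, 4 * hidden)
        self.b = np.zeros(4 * hidden)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias: remember by default

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        T, B, _ = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((T, B, H))
        cache = {"X": X, "i": np.empty((T, B, H)), "f": np.empty((T, B, H)),
                 "g": np.empty((T, B, H)), "o": np.empty((T, B, H)),
                 "c": np.empty((T, B, H)), "c_prev": np.empty((T, B, H)),
                 "h_prev": np.empty((T, B, H))}
        for t in range(T):
            z = X[t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            cache["h_prev"][t] = h
            cache["c_prev"][t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            hs[t] = h
            cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t] = i, f, g, o
            cache["c"][t] = c
        return hs, cache

    def backward(self, dH: np.ndarray, cache: dict) -> tuple[np.ndarray, list[np.ndarray]]:
        """Given dLoss/d(hidden outputs), return dLoss/dX and parameter grads."""
        X = cache["X"]
        T, B, _ = X.shape
        H = self.hidden
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            c, c_prev, h_prev = cache["c"][t], cache["c_prev"][t], cache["h_prev"][t]
            tanh_c = np.tanh(c)
            dh = dH[t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c * tanh_c) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dWx += X[t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dX, [dWx, dWh, db]


def _reverse_indices(lengths: np.ndarray, T: int) -> np.ndarray:
    """(T, B) gather indices that reverse each sequence within its own length
    and leave padding in place."""
    B = len(lengths)
    idx = np.tile(np.arange(T)[:, None], (1, B))
    for b, L in enumerate(lengths):
        idx[:L, b] = np.arange(L - 1, -1, -1)
    return idx


class SequenceNet:
    """Stacked LSTM + linear softmax head for per-epoch sequence labelling."""

    def __init__(self, n_features: int, n_classes: int, hidden: int = 64,
                 n_layers: int = 2, bidirectional: bool = False,
                 dropout: float = 0.25, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.n_classes = n_classes
        self.hidden = hidden
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.dropout = dropout
        self.layers: list[list[_LSTMLayer]] = []
        d_in = n_features
        out_mult = 2 if bidirectional else 1
        for _ in range(n_layers):
            dirs = [_LSTMLayer(d_in, hidden, rng)]
            if bidirectional:
                dirs.append(_LSTMLayer(d_in, hidden, rng))
            self.layers.append(dirs)
            d_in = hidden * out_mult
        self.W_out = _glorot(rng, d_in, n_classes)
        self.b_out = np.zeros(n_classes)

    # -- parameter plumbing ------------------------------------------------

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for dirs in self.layers:
            for layer in dirs:
                out.extend(layer.params())
        out.extend([self.W_out, self.b_out])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, lengths: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> tuple[np.ndarray, list]:
        T = X.shape[0]
        h = X
        caches = []
        for li, dirs in enumerate(self.layers):
            fwd_h, fwd_cache = dirs[0].forward(h)
            if self.bidirectional:
                ridx = _reverse_indices(lengths, T)
                cols = np.arange(h.shape[1])[None, :]
                h_rev = h[ridx, cols]
                bwd_h_r, bwd_cache = dirs[1].forward(h_rev)
                bwd_h = bwd_h_r[ridx, cols]
                out = np.concatenate([fwd_h, bwd_h], axis=2)
                caches.append((fwd_cache, bwd_cache, ridx))
            else:
                out = fwd_h
                caches.append((fwd_cache, None, None))
            if train and self.dropout > 0 and li < self.n_layers - 1:
                assert rng is not None
                keep = (rng.random(out.shape) >= self.dropout) / (1.0 - self.dropout)
                out = out * keep
                caches[-1] = (*caches[-1], keep)
            else:
                caches[-1] = (*caches[-1], None)
            h = out
        logits = h @ self.W_out + self.b_out
        caches.append(h)
        return logits, caches

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict_proba(self, X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(X, lengths, train=False, rng=None)
        return self._softmax(logits)

    def loss(self, X: np.ndarray, y: np.ndarray, lengths: np.ndarray,
             class_weights: np.ndarray) -> float:
        probs = self.predict_proba(X, lengths)
        return self._masked_ce(probs, y, lengths, class_weights)[0]

    @staticmethod
    def _loss_mask(y: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        T, B = y.shape
        return (np.arange(T)[:, None] < lengths[None, :]).astype(float)

    def _masked_ce(self, probs: np.ndarray, y: np.ndarray, lengths: np.ndarray,
                   class_weights: np.ndarray) -> tuple[float, np.ndarray, float]:
        mask = self._loss_mask(y, lengths)
        w = class_weights[np.clip(y, 0, None)] * mask
        Z = max(w.sum(), 1e-12)
        T, B = y.shape
        p_true = probs[np.arange(T)[:, None], np.arange(B)[None, :], np.clip(y, 0, None)]
        loss = float(np.sum(-np.log(np.maximum(p_true, 1e-12)) * w) / Z)
        return loss, w, Z

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, lengths: np.ndarray,
                       class_weights: np.ndarray, rng: np.random.Generator,
                       ) -> tuple[float, list[np.ndarray]]:
        """Class-weighted masked cross-entropy and grads for all parameters
        (same order as :meth:`params`)."""
        logits, caches = self._forward(X, lengths, train=True, rng=rng)
        probs = self._softmax(logits)
        loss, w, Z = self._masked_ce(probs, y, lengths, class_weights)
        T, B, C = probs.shape
        dlogits = probs.copy()
        dlogits[np.arange(T)[:, None], np.arange(B)[None, :], np.clip(y, 0, None)] -= 1.0
        dlogits *= (w / Z)[:, :, None]

        h_last = caches[-1]
        dW_out = np.tensordot(h_last, dlogits, axes=([0, 1], [0, 1]))
        db_out = dlogits.sum(axis=(0, 1))
        dh = dlogits @ self.W_out.T

        grads_rev: list[np.ndarray] = []
        for li in range(self.n_layers - 1, -1, -1):
            fwd_cache, bwd_cache, ridx, keep = caches[li]
            if keep is not None:
                dh = dh * keep
            if self.bidirectional:
                H = self.hidden
                cols = np.arange(B)[None, :]
                dfwd = dh[:, :, :H]
                dbwd = dh[:, :, H:]
                dX_f, g_f = self.layers[li][0].backward(dfwd, fwd_cache)
                dbwd_rev = dbwd[ridx, cols]
                dX_b_r, g_b = self.layers[li][1].backward(dbwd_rev, bwd_cache)
                dX_b = dX_b_r[ridx, cols]
                dh = dX_f + dX_b
                grads_rev.extend(reversed(g_b))
                grads_rev.extend(reversed(g_f))
            else:
                dX_f, g_f = self.layers[li][0].backward(dh, fwd_cache)
                dh = dX_f
                grads_rev.extend(reversed(g_f))
        grads = list(reversed(grads_rev)) + [dW_out, db_out]
        return loss, grads


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_clip: float = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.grad_clip > 0:
            norm = math.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if norm > self.grad_clip:
                scale = self.grad_clip / norm
                grads = [g * scale for g in grads]
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
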