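"""Minimal seeded numpy implementation of a 1-D convolutional network.

Supports exactly what the fitness classifier needs: a stack of same-padding
conv1d + ReLU layers over one-hot encoded peptides, an optional dropout on
the flattened features, a dense head producing one logit, binary
cross-entropy, and Adam.  Everything is float32 and driven by an explicit
``numpy.random.Generator`` so training is bit-reproducible for a fixed seed.

Array layout is ``(batch, width, channels)`` throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["ConvNet"]


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class ConvNet:
    """Conv1d stack + flatten + dense head emitting a single logit."""

    def __init__(
        self,
        in_width: int,
        in_channels: int,
        n_conv_layers: int,
        channels: int,
        kernel_size: int = 3,
        dropout: float = 0.0,
        seed: int = 0,
    ):
        if n_conv_layers < 1:
            raise ValueError("need at least one convolutional layer")
        if channels < 1 or in_width < 1 or in_channels < 1:
            raise ValueError("all layer widths must be positive")
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding conv)")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.in_width = in_width
        self.in_channels = in_channels
        self.n_conv_layers = n_conv_layers
        self.channels = channels
        self.kernel_size = kernel_size
        self.dropout = dropout

        rng = np.random.default_rng(seed)
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in = in_channels
        for _ in range(n_conv_layers):
            fan_in = kernel_size * c_in
            self.conv_w.append(_he_init(rng, fan_in, (fan_in, channels)))
            self.conv_b.append(np.zeros(channels, dtype=np.float32))
            c_in = channels
        head_in = in_width * channels
        self.head_w = _he_init(rng, head_in, (head_in,))
        self.head_b = np.float32(0.0)

        self._adam_m = [np.zeros_like(p) for p in self._params()]
        self._adam_v = [np.zeros_like(p) for p in self._params()]
        self._adam_t = 0

    # -- parameter bookkeeping -------------------------------------------
    def _params(self) -> list[np.ndarray]:
        return [*self.conv_w, *self.conv_b, self.head_w,
                np.atleast_1d(self.head_b)]

    def n_parameters(self) -> int:
        """Total trainable parameter count."""
        return int(sum(p.size for p in self._params()))

    def state_dict(self) -> dict:
        d = {f"conv_w{i}": w for i, w in enumerate(self.conv_w)}
        d.update({f"conv_b{i}": b for i, b in enumerate(self.conv_b)})
        d["head_w"] = self.head_w
        d["head_b"] = np.atleast_1d(self.head_b)
        return d

    def load_state_dict(self, d: dict) -> None:
        self.conv_w = [np.asarray(d[f"conv_w{i}"], dtype=np.float32)
                       for i in range(self.n_conv_layers)]
        self.conv_b = [np.asarray(d[f"conv_b{i}"], dtype=np.float32)
                       for i in range(self.n_conv_layers)]
        self.head_w = np.asarray(d["head_w"], dtype=np.float32)
        self.head_b = np.float32(np.asarray(d["head_b"]).reshape(()))

    # -- forward / backward ----------------------------------------------
    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, W, C) -> (B, W, k*C) with zero same-padding."""
        b, w, c = x.shape
        p = self.kernel_size // 2
        xp = np.zeros((b, w + 2 * p, c), dtype=np.float32)
        xp[:, p:-p or None, :] = x
        cols = np.empty((b, w, self.kernel_size * c), dtype=np.float32)
        for i in range(self.kernel_size):
            cols[:, :, i * c:(i + 1) * c] = xp[:, i:i + w, :]
        return cols

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return logits (B,) and, when ``train``, the cache for backward."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        cache = {"cols": [], "acts": []} if train else None
        h = x
        for w_mat, b_vec in zip(self.conv_w, self.conv_b):
            cols = self._im2col(h)
            z = cols @ w_mat + b_vec
            h = np.maximum(z, 0.0)
            if train:
                cache["cols"].append(cols)
                cache["acts"].append(h)
        b = h.shape[0]
        flat = h.reshape(b, -1)
        if train and self.dropout > 0.0:
            mask = (rng.random(flat.shape) >= self.dropout).astype(np.float32)
            flat = flat * mask / (1.0 - self.dropout)
            cache["drop_mask"] = mask
        logits = flat @ self.head_w + self.head_b
        if train:
            cache["flat"] = flat
        return (logits, cache) if train else logits

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator):
        """Mean binary cross-entropy and gradients for one minibatch."""
        logits, cache = self.forward(x, train=True, rng=rng)
        b = x.shape[0]
        p = expit(logits)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dlogits = ((p - y) / b).astype(np.float32)

        g_head_w = cache["flat"].T @ dlogits
        g_head_b = np.atleast_1d(dlogits.sum().astype(np.float32))
        dflat = np.outer(dlogits, self.head_w)
        if self.dropout > 0.0:
            dflat = dflat * cache["drop_mask"] / (1.0 - self.dropout)
        dh = dflat.reshape(b, self.in_width, self.channels)

        g_conv_w = [None] * self.n_conv_layers
        g_conv_b = [None] * self.n_conv_layers
        for li in range(self.n_conv_layers - 1, -1, -1):
            dz = dh * (cache["acts"][li] > 0)
            cols = cache["cols"][li]
            kc = cols.shape[2]
            g_conv_w[li] = cols.reshape(-1, kc).T @ dz.reshape(-1, self.channels)
            g_conv_b[li] = dz.sum(axis=(0, 1)).astype(np.float32)
            if li > 0:
                dcols = dz @ self.conv_w[li].T
                c = self.channels
                w = self.in_width
                pad = self.kernel_size // 2
                dxp = np.zeros((b, w + 2 * pad, c), dtype=np.float32)
                for i in range(self.kernel_size):
                    dxp[:, i:i + w, :] += dcols[:, :, i * c:(i + 1) * c]
                dh = dxp[:, pad:-pad or None, :]
        grads = [*g_conv_w, *g_conv_b, g_head_w, g_head_b]
        return loss, grads

    def adam_step(self, grads, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        params = self._params()
        for i, (p, g) in enumerate(zip(params, grads)):
            m = self._adam_m[i]
            v = self._adam_v[i]
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mh = m / (1 - beta1 ** t)
            vh = v / (1 - beta2 ** t)
            p -= (lr * mh / (np.sqrt(vh) + eps)).astype(np.float32)
        # head bias is a scalar wrapped on the fly; write it back explicitly
        self.head_b = np.float32(params[-1][0])

    def predict_logits(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = np.empty(x.shape[0], dtype=np.float32)
        for s in range(0, x.shape[0], batch_size):
            out[s:s + batch_size] = self.forward(x[s:s + batch_size])
        return out
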