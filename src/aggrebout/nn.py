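"""Minimal convolutional network on numpy.

A deliberately small architecture for frame-level binary classification:
a stack of 3x3 same-padding convolutions with ReLU and 2x2 max-pooling,
global average pooling, and a single logistic output unit.  Training is
plain Adam on a class-weighted binary cross-entropy.  Everything is
deterministic given the RNG handed in, and weights round-trip through
``state_dict`` / ``load_state_dict`` bit-identically.

Convolutions are lowered to a single matrix product per layer (im2col),
which keeps CPU training fast; compute runs in float32 by default (pass
``dtype=np.float64`` for, e.g., finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallConvNet", "Adam", "weighted_bce_with_logits"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, C*9, H*W) patch matrix for a 3x3 same-padding conv.

    Tap order is row-major over the 3x3 kernel, matching the (F, C*9)
    weight layout.
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            cols[:, :, i * 3 + j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * 9, h * w)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    d = dcols.reshape(n, c, 9, h, w)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i * 3 + j]
    return dxp[:, :, 1:-1, 1:-1]


def _pool_forward(x: np.ndarray):
    """2x2 max-pool (stride 2) via pairwise maxima; odd edges are trimmed."""
    n, f, h, w = x.shape
    ht, wt = (h // 2) * 2, (w // 2) * 2
    a = x[:, :, :ht, :wt]
    m = np.maximum(a[:, :, 0::2, :], a[:, :, 1::2, :])
    out = np.maximum(m[:, :, :, 0::2], m[:, :, :, 1::2])
    return out, (a, out, x.shape)


def _pool_backward(dout: np.ndarray, cache) -> np.ndarray:
    a, out, shape = cache
    up = np.repeat(np.repeat(out, 2, axis=2), 2, axis=3)
    g = (a == up) * np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3)
    n, f, h, w = shape
    ht, wt = (h // 2) * 2, (w // 2) * 2
    if (ht, wt) == (h, w):
        return g
    dx = np.zeros(shape, dtype=dout.dtype)
    dx[:, :, :ht, :wt] = g
    return dx


class SmallConvNet:
    """Conv(3x3)->ReLU->pool blocks, global average pool, logistic unit."""

    def __init__(
        self,
        in_channels: int,
        conv_filters: tuple[int, ...] = (8, 16, 32),
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.conv_filters = tuple(conv_filters)
        self.dtype = dtype
        self.params: dict[str, np.ndarray] = {}
        c = in_channels
        for k, f in enumerate(self.conv_filters):
            scale = np.sqrt(2.0 / (c * 9))  # He init for ReLU
            self.params[f"w{k}"] = rng.normal(0, scale, (f, c * 9)).astype(dtype)
            self.params[f"b{k}"] = np.zeros(f, dtype=dtype)
            c = f
        self.params["wd"] = rng.normal(0, np.sqrt(1.0 / c), (c,)).astype(dtype)
        self.params["bd"] = np.zeros(1, dtype=dtype)

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, need_cache: bool = False):
        """Return logits (N,); with ``need_cache`` also the backprop cache."""
        cache: list = []
        h = np.ascontiguousarray(x, dtype=self.dtype)
        for k in range(len(self.conv_filters)):
            n, _, hh, ww = h.shape
            cols = _im2col(h)  # (N, C*9, H*W)
            z = np.matmul(self.params[f"w{k}"], cols)  # (N, F, H*W)
            z += self.params[f"b{k}"][:, None]
            z = z.reshape(n, self.conv_filters[k], hh, ww)
            a = np.maximum(z, 0)
            p, pc = _pool_forward(a)
            if need_cache:
                cache.append((h.shape, cols, z > 0, pc))
            h = p
        gap = h.mean(axis=(2, 3))  # (N, F_last)
        logits = gap @ self.params["wd"] + self.params["bd"][0]
        if need_cache:
            return logits.astype(np.float64), (cache, h.shape, gap)
        return logits.astype(np.float64)

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        conv_cache, last_shape, gap = cache
        dlogits = dlogits.astype(self.dtype)
        grads: dict[str, np.ndarray] = {}
        grads["wd"] = gap.T @ dlogits
        grads["bd"] = np.array([dlogits.sum()], dtype=self.dtype)
        dgap = np.outer(dlogits, self.params["wd"])
        n, f, h, w = last_shape
        dh = np.ascontiguousarray(
            np.broadcast_to(dgap[:, :, None, None], last_shape) / (h * w),
            dtype=self.dtype,
        )
        for k in reversed(range(len(self.conv_filters))):
            in_shape, cols, relu_mask, pc = conv_cache[k]
            da = _pool_backward(dh, pc)
            dz = da * relu_mask
            nn_, ff, hh, ww = dz.shape
            dzf = dz.reshape(nn_, ff, hh * ww)
            grads[f"w{k}"] = np.matmul(dzf, cols.transpose(0, 2, 1)).sum(axis=0)
            grads[f"b{k}"] = dzf.sum(axis=(0, 2))
            if k > 0:
                dcols = np.matmul(self.params[f"w{k}"].T, dzf)
                dh = _col2im(dcols, in_shape)
        return grads

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = np.empty(len(x))
        for s in range(0, len(x), batch):
            out[s : s + batch] = 1.0 / (
                1.0 + np.exp(-self.forward(x[s : s + batch]))
            )
        return out

    # ---- persistence ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=self.dtype).reshape(
                self.params[k].shape
            )


def weighted_bce_with_logits(
    logits: np.ndarray, y: np.ndarray, pos_weight: float
) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy on logits; returns (loss, dlogits)."""
    w = np.where(y == 1, pos_weight, 1.0)
    total = w.sum()
    sp = np.logaddexp(0.0, logits)  # stable softplus
    loss = float(np.sum(w * (sp - y * logits)) / total)
    sig = 1.0 / (1.0 + np.exp(-logits))
    dlogits = w * (sig - y) / total
    return loss, dlogits


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(
                params[k].dtype
            )
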