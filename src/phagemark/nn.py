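"""Minimal NumPy building blocks for the sequence CNN.

The architecture is small enough (one convolution, global max-pooling, two
dense layers) that forward and backward passes reduce to a handful of BLAS
calls.  Global max-pooling makes the convolutional backward pass cheap:
only the argmax window of each filter receives gradient, so the weight
gradient is a gather followed by one small einsum.

All functions are pure: parameters live in a plain dict of float32 arrays
and randomness comes from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

PARAM_NAMES = ("W_conv", "b_conv", "W_dense", "b_dense", "W_out", "b_out")


def init_params(
    kernel_len: int, n_filters: int, n_dense: int, n_classes: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """He-initialised weights for the ReLU layers, Glorot for the output."""
    c_in = kernel_len * 20
    p = {
        "W_conv": rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, n_filters)),
        "b_conv": np.zeros(n_filters),
        "W_dense": rng.normal(0.0, np.sqrt(2.0 / n_filters), size=(n_filters, n_dense)),
        "b_dense": np.zeros(n_dense),
        "W_out": rng.normal(0.0, np.sqrt(1.0 / n_dense), size=(n_dense, n_classes)),
        "b_out": np.zeros(n_classes),
    }
    return {k: v.astype(np.float32) for k, v in p.items()}


def _im2col(X: np.ndarray, kernel_len: int) -> np.ndarray:
    """(n, L, 20) -> (n, L-k+1, k*20) windows along the sequence axis."""
    win = sliding_window_view(X, kernel_len, axis=1)  # (n, P, 20, k)
    n, P = win.shape[0], win.shape[1]
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n, P, kernel_len * 20)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    kernel_len: int,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    want_cache: bool = False,
):
    """Run the network; returns probabilities and, optionally, the cache
    needed by :func:`backward`.

    Dropout (inverted scaling) is applied after pooling and after the first
    dense layer, only when ``dropout_rate > 0`` and an ``rng`` is supplied
    (i.e. during training); inference is deterministic.
    """
    Xw = _im2col(np.asarray(X, dtype=np.float32), kernel_len)
    Zc = Xw @ params["W_conv"] + params["b_conv"]  # (n, P, F)
    Ac = np.maximum(Zc, 0.0)
    amax = Ac.argmax(axis=1)  # (n, F)
    pool = np.take_along_axis(Ac, amax[:, None, :], axis=1)[:, 0, :]

    training = dropout_rate > 0.0 and rng is not None
    keep = 1.0 - dropout_rate
    if training:
        mask1 = (rng.random(pool.shape) < keep).astype(np.float32) / keep
        h0 = pool * mask1
    else:
        mask1 = None
        h0 = pool
    Zd = h0 @ params["W_dense"] + params["b_dense"]
    Ad = np.maximum(Zd, 0.0)
    if training:
        mask2 = (rng.random(Ad.shape) < keep).astype(np.float32) / keep
        h1 = Ad * mask2
    else:
        mask2 = None
        h1 = Ad
    logits = h1 @ params["W_out"] + params["b_out"]
    probs = softmax(logits)
    if not want_cache:
        return probs
    cache = dict(Xw=Xw, amax=amax, pool=pool, mask1=mask1, h0=h0, Zd=Zd,
                 mask2=mask2, h1=h1, probs=probs)
    return probs, cache


def cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy (natural log) against integer labels."""
    p = np.clip(probs[np.arange(len(y)), y], eps, None)
    return float(-np.log(p).mean())


def backward(
    params: dict[str, np.ndarray], cache: dict, y: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of mean cross-entropy w.r.t. every parameter."""
    n = len(y)
    probs = cache["probs"]
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    grads: dict[str, np.ndarray] = {}
    grads["W_out"] = cache["h1"].T @ dlogits
    grads["b_out"] = dlogits.sum(axis=0)
    dh1 = dlogits @ params["W_out"].T
    if cache["mask2"] is not None:
        dh1 = dh1 * cache["mask2"]
    dZd = dh1 * (cache["Zd"] > 0)
    grads["W_dense"] = cache["h0"].T @ dZd
    grads["b_dense"] = dZd.sum(axis=0)
    dh0 = dZd @ params["W_dense"].T
    if cache["mask1"] is not None:
        dh0 = dh0 * cache["mask1"]
    # gradient reaches the conv layer only through each filter's max window,
    # and only where that max is strictly positive (ReLU)
    dpool = dh0 * (cache["pool"] > 0)
    Xg = np.take_along_axis(
        cache["Xw"][:, :, None, :], cache["amax"][:, None, :, None], axis=1
    )[:, 0, :, :]  # (n, F, C)
    grads["W_conv"] = np.einsum("nfc,nf->cf", Xg, dpool)
    grads["b_conv"] = dpool.sum(axis=0)
    return grads


class Adam:
    """Adam optimiser over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= (self.lr * (self.m[k] / b1t)
                          / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(np.float32)


def minibatches(n: int, batch_size: int, rng: np.random.Generator) -> Iterator[np.ndarray]:
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
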