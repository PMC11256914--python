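"""Minimal numpy neural-network primitives with explicit backprop.

All networks in this package (the conditional GAN's generator and
discriminator, the common-subspace autoencoder, and the per-phylum 1D
CNNs) are small multilayer perceptrons or single-conv-block networks, so
they are implemented directly on numpy arrays: each layer exposes
``forward`` returning a cache and ``backward`` consuming it.  Parameters
live in plain dicts of float64 arrays, which keeps serialisation and
determinism trivial (all randomness flows through an explicit
``numpy.random.Generator``).

Training is plain SGD; learning-rate and batch-size defaults live with
the calling modules, not here.
"""

from __future__ import annotations

import numpy as np

LEAK = 0.2  # LeakyReLU slope used throughout


# ---------------------------------------------------------------------------
# dense layers


def dense_init(rng: np.random.Generator, fan_in: int, fan_out: int,
               scale: float | None = None) -> dict:
    """He-style initialisation; ``scale`` overrides the default std."""
    std = scale if scale is not None else np.sqrt(2.0 / fan_in)
    return {
        "W": rng.normal(0.0, std, size=(fan_in, fan_out)),
        "b": np.zeros(fan_out),
    }


def dense_forward(p: dict, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return x @ p["W"] + p["b"], x


def dense_backward(p: dict, x: np.ndarray, dy: np.ndarray
                   ) -> tuple[np.ndarray, dict]:
    grads = {"W": x.T @ dy, "b": dy.sum(axis=0)}
    return dy @ p["W"].T, grads


# ---------------------------------------------------------------------------
# activations (forward returns (y, cache); backward maps dy -> dx)


def act_forward(kind: str, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if kind == "linear":
        return z, z
    if kind == "leaky_relu":
        y = np.where(z > 0, z, LEAK * z)
        return y, z
    if kind == "tanh":
        y = np.tanh(z)
        return y, y
    if kind == "relu":
        y = np.maximum(z, 0.0)
        return y, z
    if kind == "sigmoid":
        y = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return y, y
    if kind == "softmax":
        zs = z - z.max(axis=-1, keepdims=True)
        e = np.exp(zs)
        y = e / e.sum(axis=-1, keepdims=True)
        return y, y
    raise ValueError(f"unknown activation {kind!r}")


def act_backward(kind: str, cache: np.ndarray, dy: np.ndarray) -> np.ndarray:
    if kind == "linear":
        return dy
    if kind == "leaky_relu":
        return np.where(cache > 0, dy, LEAK * dy)
    if kind == "tanh":
        return dy * (1.0 - cache**2)
    if kind == "relu":
        return np.where(cache > 0, dy, 0.0)
    if kind == "sigmoid":
        return dy * cache * (1.0 - cache)
    if kind == "softmax":
        y = cache
        return (dy - (dy * y).sum(axis=-1, keepdims=True)) * y
    raise ValueError(f"unknown activation {kind!r}")


# ---------------------------------------------------------------------------
# multilayer perceptron


class MLP:
    """Fully connected net: dims[0] -> ... -> dims[-1].

    ``hidden`` is the activation of every layer but the last, ``out`` the
    head activation.  Parameters are a list of {"W", "b"} dicts.
    """

    def __init__(self, dims: list[int], hidden: str = "leaky_relu",
                 out: str = "linear", rng: np.random.Generator | None = None,
                 params: list[dict] | None = None):
        self.dims = list(dims)
        self.hidden = hidden
        self.out = out
        if params is not None:
            self.params = params
        else:
            assert rng is not None
            self.params = [
                dense_init(rng, dims[i], dims[i + 1])
                for i in range(len(dims) - 1)
            ]

    def _acts(self) -> list[str]:
        n = len(self.params)
        return [self.hidden] * (n - 1) + [self.out]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        caches = []
        h = x
        for p, kind in zip(self.params, self._acts()):
            z, xc = dense_forward(p, h)
            h, ac = act_forward(kind, z)
            caches.append((xc, ac))
        return h, caches

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, caches: list, dout: np.ndarray
                 ) -> tuple[np.ndarray, list[dict]]:
        grads: list[dict] = [None] * len(self.params)  # type: ignore[list-item]
        d = dout
        for i in reversed(range(len(self.params))):
            xc, ac = caches[i]
            dz = act_backward(self._acts()[i], ac, d)
            d, grads[i] = dense_backward(self.params[i], xc, dz)
        return d, grads

    def step(self, grads: list[dict], lr: float) -> None:
        for p, g in zip(self.params, grads):
            p["W"] -= lr * g["W"]
            p["b"] -= lr * g["b"]

    def param_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.params):
            out[f"W{i}"] = p["W"]
            out[f"b{i}"] = p["b"]
        return out

    @classmethod
    def from_arrays(cls, dims, hidden, out, arrays: dict) -> "MLP":
        params = []
        i = 0
        while f"W{i}" in arrays:
            params.append({"W": np.asarray(arrays[f"W{i}"]),
                           "b": np.asarray(arrays[f"b{i}"])})
            i += 1
        return cls(dims, hidden=hidden, out=out, params=params)


# ---------------------------------------------------------------------------
# 1-D convolution (single input channel) + max pooling


def conv1d_init(rng: np.random.Generator, n_filters: int, kernel: int) -> dict:
    std = np.sqrt(2.0 / kernel)
    return {"W": rng.normal(0.0, std, size=(n_filters, kernel)),
            "b": np.zeros(n_filters)}


def conv1d_forward(p: dict, x: np.ndarray, stride: int = 1
                   ) -> tuple[np.ndarray, np.ndarray]:
    """x: (batch, length) -> (batch, n_filters, n_positions)."""
    kernel = p["W"].shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=1)
    windows = windows[:, ::stride, :]  # (b, pos, kernel)
    out = (windows @ p["W"].T).transpose(0, 2, 1) + p["b"][None, :, None]
    return out, windows


def conv1d_backward(p: dict, windows: np.ndarray, x_len: int, stride: int,
                    dy: np.ndarray) -> tuple[np.ndarray, dict]:
    """dy: (batch, n_filters, n_positions) -> dx (batch, x_len) and grads."""
    b, f, pos = dy.shape
    kernel = p["W"].shape[1]
    dy_bpf = dy.transpose(0, 2, 1)  # (b, pos, f)
    grads = {
        "W": dy_bpf.reshape(-1, f).T @ windows.reshape(-1, kernel),
        "b": dy.sum(axis=(0, 2)),
    }
    dwin = dy_bpf @ p["W"]  # (b, pos, kernel)
    dx = np.zeros((b, x_len))
    # scatter by kernel offset: for offset k the positions hit a strided slice
    for k in range(kernel):
        dx[:, k:k + stride * pos:stride] += dwin[:, :, k]
    return dx, grads


def maxpool1d_forward(x: np.ndarray, size: int = 2
                      ) -> tuple[np.ndarray, tuple]:
    """x: (batch, channels, length); truncates a ragged tail."""
    b, c, ln = x.shape
    n = ln // size
    if n == 0:  # shorter than the pool window: pass through
        return x, (x.shape, None)
    xt = x[:, :, : n * size].reshape(b, c, n, size)
    if size == 2:  # fast path: pairwise maximum
        idx = (xt[..., 1] > xt[..., 0]).astype(np.intp)
        out = np.maximum(xt[..., 0], xt[..., 1])
        return out, (x.shape, idx)
    idx = xt.argmax(axis=3)
    out = np.take_along_axis(xt, idx[..., None], axis=3)[..., 0]
    return out, (x.shape, idx)


def maxpool1d_backward(cache: tuple, dy: np.ndarray, size: int = 2
                       ) -> np.ndarray:
    shape, idx = cache
    if idx is None:
        return dy
    b, c, ln = shape
    n = ln // size
    dxt = np.zeros((b, c, n, size))
    np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=3)
    dx = np.zeros(shape)
    dx[:, :, : n * size] = dxt.reshape(b, c, n * size)
    return dx
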