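"""Minimal NumPy neural-network core: dense/conv layers, Adam, losses.

Everything is float64-by-default for the small tabular nets and float32 for
convolutions; all randomness flows through an explicit ``numpy.random.Generator``
so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "relu",
    "sigmoid",
    "softmax",
    "cross_entropy",
    "Dense",
    "MLP",
    "Adam",
    "conv3x3_forward",
    "conv3x3_backward",
    "maxpool2_forward",
    "maxpool2_backward",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Dense:
    """Affine layer ``x @ W + b`` with He-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        bound = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W + self.b

    def backward(self, x: np.ndarray, dout: np.ndarray):
        dW = x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.W.T
        return dx, dW, db


class MLP:
    """Fully connected net with ReLU hidden layers.

    ``output`` selects the final activation: ``"linear"`` (classification
    logits) or ``"sigmoid"`` (reconstructions constrained to [0, 1]).
    """

    def __init__(self, widths: tuple[int, ...], rng: np.random.Generator,
                 output: str = "linear", dtype=np.float64) -> None:
        if len(widths) < 2:
            raise ValueError("MLP needs at least input and output widths")
        if output not in ("linear", "sigmoid"):
            raise ValueError(f"unknown output activation {output!r}")
        self.widths = tuple(int(w) for w in widths)
        self.output = output
        self.layers = [
            Dense(a, b, rng, dtype=dtype) for a, b in zip(widths[:-1], widths[1:])
        ]

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend((layer.W, layer.b))
        return out

    def weight_matrices(self) -> list[np.ndarray]:
        return [layer.W for layer in self.layers]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, return_hidden: bool = False):
        """Forward pass; with ``return_hidden`` also returns all activations.

        The activations list is ``[input, h1, ..., output]`` (post-activation).
        """
        acts = [x]
        h = x
        for i, layer in enumerate(self.layers):
            z = layer.forward(h)
            if i < len(self.layers) - 1:
                h = relu(z)
            elif self.output == "sigmoid":
                h = sigmoid(z)
            else:
                h = z
            acts.append(h)
        return (h, acts) if return_hidden else h

    def backward(self, acts: list[np.ndarray], dout: np.ndarray) -> list[np.ndarray]:
        """Gradient of loss w.r.t. parameters given d(loss)/d(output).

        ``dout`` must already include the output-activation derivative when
        ``output == "linear"``; for sigmoid output it is d(loss)/d(post-sigmoid)
        and the sigmoid derivative is applied here.
        """
        grads: list[np.ndarray | None] = [None] * (2 * len(self.layers))
        d = dout
        if self.output == "sigmoid":
            y = acts[-1]
            d = d * y * (1.0 - y)
        for i in range(len(self.layers) - 1, -1, -1):
            x_in = acts[i]
            dx, dW, db = self.layers[i].backward(x_in, d)
            grads[2 * i] = dW
            grads[2 * i + 1] = db
            if i > 0:
                dx = dx * (acts[i] > 0)  # ReLU derivative of the hidden act
            d = dx
        return grads  # type: ignore[return-value]


class Adam:
    """Adam optimizer updating parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# 3x3 same-padding convolution via im2col, and 2x2 max pooling
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, 9*C) column matrix for a 3x3 same-pad conv."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (N, H, W, C, 3, 3) -> (N, H, W, 3, 3, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(n * h * w, 9 * c)


def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 stride-1 same-padding convolution.

    ``x``: (N,H,W,Cin); ``W``: (9*Cin, Cout) in im2col layout; ``b``: (Cout,).
    Returns ``(out, cols)`` where cols is the cached column matrix.
    """
    n, h, w, _ = x.shape
    cols = _im2col3(x)
    out = (cols @ W + b).reshape(n, h, w, W.shape[1])
    return out, cols


def conv3x3_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray,
                     x_shape: tuple[int, ...]):
    """Backward pass of :func:`conv3x3_forward`; returns (dx, dW, db)."""
    n, h, w, c_in = x_shape
    c_out = W.shape[1]
    dflat = dout.reshape(n * h * w, c_out)
    dW = cols.T @ dflat
    db = dflat.sum(axis=0)
    dcols = (dflat @ W.T).reshape(n, h, w, 3, 3, c_in)
    dxp = np.zeros((n, h + 2, w + 2, c_in), dtype=dout.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
    return dxp[:, 1:-1, 1:-1, :], dW, db


def maxpool2_forward(x: np.ndarray):
    """2x2 stride-2 max pooling; H and W must be even. Returns (out, argmax)."""
    n, h, w, c = x.shape
    r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    r = r.reshape(n, h // 2, w // 2, 4, c)
    arg = r.argmax(axis=3)
    out = np.take_along_axis(r, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, arg


def maxpool2_backward(dout: np.ndarray, arg: np.ndarray, x_shape: tuple[int, ...]):
    n, h, w, c = x_shape
    dr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dout.dtype)
    np.put_along_axis(dr, arg[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dr = dr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return dr.reshape(n, h, w, c)
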