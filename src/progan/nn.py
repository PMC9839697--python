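"""Minimal fully-connected network machinery for the WGAN.

Both networks are three-layer perceptrons with leaky-ReLU activations after
the first and second weight layers and a linear output:

    y = W3 @ phi(W2 @ phi(W1 @ x + b1) + b2) + b3

Implemented directly on numpy arrays with hand-written backpropagation. The
gradient penalty of the critic needs the derivative, with respect to the
critic's parameters, of the norm of the critic's input gradient; for a
piecewise-linear activation the activation derivatives are locally constant,
so this "double backprop" has the closed form implemented in
:meth:`MLP.penalty_param_grads` (bias gradients of the penalty are zero
almost everywhere, as in automatic differentiation).
"""
from __future__ import annotations

import numpy as np


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def leaky_relu_deriv(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


class MLP:
    """Three-layer perceptron ``in -> hidden -> hidden -> out``.

    Weights are initialized uniformly in ``[-init_range, init_range]``;
    biases start at zero.
    """

    def __init__(self, sizes: tuple[int, int, int, int], slope: float,
                 init_range: float, rng: np.random.Generator):
        if len(sizes) != 4:
            raise ValueError("expected (in, hidden, hidden, out) sizes")
        self.sizes = tuple(int(s) for s in sizes)
        self.slope = float(slope)
        n_in, h1, h2, n_out = self.sizes
        r = init_range
        self.params = {
            "W1": rng.uniform(-r, r, size=(n_in, h1)),
            "b1": np.zeros(h1),
            "W2": rng.uniform(-r, r, size=(h1, h2)),
            "b2": np.zeros(h2),
            "W3": rng.uniform(-r, r, size=(h2, n_out)),
            "b3": np.zeros(n_out),
        }

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())

    @staticmethod
    def count_params(sizes: tuple[int, int, int, int]) -> int:
        n_in, h1, h2, n_out = sizes
        return (n_in * h1 + h1) + (h1 * h2 + h2) + (h2 * n_out + n_out)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(params[k], dtype=float)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False):
        """Batch forward pass; ``x`` is (batch, in)."""
        p = self.params
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.sizes[0]:
            raise ValueError(
                f"input shape {x.shape} incompatible with input size {self.sizes[0]}"
            )
        a1 = x @ p["W1"] + p["b1"]
        h1 = leaky_relu(a1, self.slope)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = leaky_relu(a2, self.slope)
        y = h2 @ p["W3"] + p["b3"]
        if not cache:
            return y
        return y, {"x": x, "a1": a1, "h1": h1, "a2": a2, "h2": h2}

    def backward(self, cache: dict, dy: np.ndarray):
        """Gradients of a scalar loss given ``dy = dL/dy``.

        Returns ``(param_grads, dx)``.
        """
        p = self.params
        d2 = leaky_relu_deriv(cache["a2"], self.slope)
        d1 = leaky_relu_deriv(cache["a1"], self.slope)
        gW3 = cache["h2"].T @ dy
        gb3 = dy.sum(axis=0)
        dh2 = dy @ p["W3"].T
        da2 = dh2 * d2
        gW2 = cache["h1"].T @ da2
        gb2 = da2.sum(axis=0)
        dh1 = da2 @ p["W2"].T
        da1 = dh1 * d1
        gW1 = cache["x"].T @ da1
        gb1 = da1.sum(axis=0)
        dx = da1 @ p["W1"].T
        grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3}
        return grads, dx

    # -- input gradient & gradient penalty ----------------------------------

    def input_gradient(self, x: np.ndarray):
        """Per-sample gradient of the scalar output w.r.t. the input.

        Only valid for an output dimension of 1. Returns ``(g, cache)`` with
        ``g`` of shape (batch, in).
        """
        if self.sizes[3] != 1:
            raise ValueError("input_gradient requires scalar output")
        p = self.params
        _, cache = self.forward(x, cache=True)
        d1 = leaky_relu_deriv(cache["a1"], self.slope)  # (B, h1)
        d2 = leaky_relu_deriv(cache["a2"], self.slope)  # (B, h2)
        w3 = p["W3"][:, 0]  # (h2,)
        v = d2 * w3  # (B, h2)
        u = d1 * (v @ p["W2"].T)  # (B, h1)
        g = u @ p["W1"].T  # (B, in)
        cache = {**cache, "d1": d1, "d2": d2, "v": v, "u": u, "g": g}
        return g, cache

    def gradient_penalty(self, x: np.ndarray):
        """Mean ``(||grad_x f(x)|| - 1)^2`` over the batch, with cache."""
        g, cache = self.input_gradient(x)
        norms = np.sqrt((g**2).sum(axis=1))
        penalty = float(np.mean((norms - 1.0) ** 2))
        cache["norms"] = norms
        return penalty, cache

    def penalty_param_grads(self, cache: dict) -> dict[str, np.ndarray]:
        """d(penalty)/d(params), treating activation slopes as locally constant.

        With ``g_b = W1 (d1_b * (W2 (d2_b * w3)))`` and
        ``P = mean_b (||g_b|| - 1)^2``, the chain rule gives outer-product
        sums over the batch; bias gradients vanish almost everywhere.
        """
        p = self.params
        g, u, v = cache["g"], cache["u"], cache["v"]
        d1, d2 = cache["d1"], cache["d2"]
        norms = cache["norms"]
        B = g.shape[0]
        safe = np.maximum(norms, 1e-12)
        s = 2.0 * (norms - 1.0) / safe / B  # (B,)
        dPdg = s[:, None] * g  # (B, in)
        gW1 = dPdg.T @ u  # (in, h1)
        dPdu = dPdg @ p["W1"]  # (B, h1)
        q = d1 * dPdu  # (B, h1): dP/d(W2 v)
        gW2 = q.T @ v  # (h1, h2)
        dPdv = q @ p["W2"]  # (B, h2)
        gw3 = (d2 * dPdv).sum(axis=0)  # (h2,)
        zeros = lambda k: np.zeros_like(p[k])
        return {
            "W1": gW1, "b1": zeros("b1"),
            "W2": gW2, "b2": zeros("b2"),
            "W3": gw3[:, None], "b3": zeros("b3"),
        }


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.5, 0.9), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Rows with zero variance yield NaN correlations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.sqrt((az**2).sum(axis=1))
    bn = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az @ bz.T) / np.outer(an, bn)
    return r
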