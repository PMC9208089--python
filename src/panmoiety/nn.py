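"""Minimal feed-forward binary classifier in numpy.

Architecture per hidden layer: Linear -> BatchNorm -> ReLU -> Dropout, with
a Linear -> sigmoid head.  Trained with Adam on binary cross entropy.  The
implementation is deliberately small and fully deterministic given a seed:
it exists so the attribution machinery can interrogate an ordinary deep
QSAR classifier without a deep-learning framework dependency.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["DenseNet", "Adam", "binary_cross_entropy", "sigmoid"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log likelihood of binary labels under probabilities p."""
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class DenseNet:
    """Fully connected net: n_inputs -> hidden_sizes -> 1 probability."""

    def __init__(
        self,
        n_inputs: int,
        hidden_sizes: Sequence[int],
        dropout_rate: float = 0.2,
        batch_norm: bool = True,
        seed: int = 0,
    ):
        if len(hidden_sizes) < 1:
            raise ValueError("at least one hidden layer is required")
        if any(h < 1 for h in hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
        self.n_inputs = int(n_inputs)
        self.hidden_sizes = [int(h) for h in hidden_sizes]
        self.dropout_rate = float(dropout_rate)
        self.batch_norm = bool(batch_norm)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        sizes = [self.n_inputs] + self.hidden_sizes + [1]
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, suited to ReLU units
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        if self.batch_norm:
            self.gamma = [np.ones(h) for h in self.hidden_sizes]
            self.beta = [np.zeros(h) for h in self.hidden_sizes]
            self.run_mean = [np.zeros(h) for h in self.hidden_sizes]
            self.run_var = [np.ones(h) for h in self.hidden_sizes]
        else:
            self.gamma = self.beta = self.run_mean = self.run_var = []

    # -- parameter plumbing --------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b + self.gamma + self.beta

    def state_dict(self) -> dict:
        return copy.deepcopy(
            {
                "W": self.W,
                "b": self.b,
                "gamma": self.gamma,
                "beta": self.beta,
                "run_mean": self.run_mean,
                "run_var": self.run_var,
            }
        )

    def load_state_dict(self, state: dict) -> None:
        for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
            setattr(self, name, copy.deepcopy(state[name]))

    # -- forward / backward --------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return (probabilities, cache).  Training mode uses batch statistics
        for normalization and applies inverted dropout with the given rng."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected input of shape (n, {self.n_inputs}), got {X.shape}"
            )
        if training and self.dropout_rate > 0 and rng is None:
            raise ValueError("training forward pass with dropout requires an rng")
        cache = {"A": [X], "Z": [], "xhat": [], "std": [], "mask": []}
        A = X
        n_hidden = len(self.hidden_sizes)
        for l in range(n_hidden):
            Z = A @ self.W[l] + self.b[l]
            cache["Z"].append(Z)
            if self.batch_norm:
                if training:
                    mu = Z.mean(axis=0)
                    var = Z.var(axis=0)
                    self.run_mean[l] = _BN_MOMENTUM * self.run_mean[l] + (1 - _BN_MOMENTUM) * mu
                    self.run_var[l] = _BN_MOMENTUM * self.run_var[l] + (1 - _BN_MOMENTUM) * var
                else:
                    mu, var = self.run_mean[l], self.run_var[l]
                std = np.sqrt(var + _BN_EPS)
                xhat = (Z - mu) / std
                H = self.gamma[l] * xhat + self.beta[l]
                cache["xhat"].append(xhat)
                cache["std"].append(std)
            else:
                H = Z
                cache["xhat"].append(None)
                cache["std"].append(None)
            A = np.maximum(H, 0.0)
            if training and self.dropout_rate > 0:
                keep = 1.0 - self.dropout_rate
                mask = (rng.random(A.shape) < keep) / keep
                A = A * mask
                cache["mask"].append(mask)
            else:
                cache["mask"].append(None)
            cache["A"].append(A)
        logits = A @ self.W[-1] + self.b[-1]
        cache["logits"] = logits
        p = sigmoid(logits[:, 0])
        return p, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities, preserving float32/float64 input.

        Batch normalization is folded into an affine rescale using the
        running statistics, so this path allocates nothing per layer beyond
        the activations themselves.
        """
        X = np.asarray(X)
        if X.dtype not in (np.float32, np.float64):
            X = X.astype(np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected input of shape (n, {self.n_inputs}), got {X.shape}"
            )
        dt = X.dtype
        A = X
        for l in range(len(self.hidden_sizes)):
            if self.batch_norm:
                scale = (self.gamma[l] / np.sqrt(self.run_var[l] + _BN_EPS)).astype(dt)
                shift = (self.beta[l] - self.run_mean[l] * scale).astype(dt)
                W = (self.W[l] * scale[None, :]).astype(dt)
                b = (self.b[l] * scale + shift).astype(dt)
            else:
                W = self.W[l].astype(dt)
                b = self.b[l].astype(dt)
            A = np.maximum(A @ W + b, 0.0)
        logits = A @ self.W[-1].astype(dt) + self.b[-1].astype(dt)
        return sigmoid(logits[:, 0].astype(np.float64))

    def backward(self, cache: dict, y: np.ndarray) -> list[np.ndarray]:
        """Gradient of mean BCE w.r.t. parameters, ordered as parameters()."""
        n = len(y)
        p = sigmoid(cache["logits"][:, 0])
        dlogits = ((p - y) / n)[:, None]
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        ggamma = [np.zeros_like(g) for g in self.gamma]
        gbeta = [np.zeros_like(g) for g in self.beta]

        gW[-1] = cache["A"][-1].T @ dlogits
        gb[-1] = dlogits.sum(axis=0)
        dA = dlogits @ self.W[-1].T
        for l in range(len(self.hidden_sizes) - 1, -1, -1):
            mask = cache["mask"][l]
            if mask is not None:
                dA = dA * mask
            # ReLU was applied to H (post-BN); recover H from the cache
            if self.batch_norm:
                H = self.gamma[l] * cache["xhat"][l] + self.beta[l]
            else:
                H = cache["Z"][l]
            dH = dA * (H > 0)
            if self.batch_norm:
                xhat = cache["xhat"][l]
                std = cache["std"][l]
                ggamma[l] = (dH * xhat).sum(axis=0)
                gbeta[l] = dH.sum(axis=0)
                dxhat = dH * self.gamma[l]
                m = dH.shape[0]
                dZ = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
                if m == 1:  # degenerate batch: normalization has no gradient
                    dZ = dxhat / std
            else:
                dZ = dH
            gW[l] = cache["A"][l].T @ dZ
            gb[l] = dZ.sum(axis=0)
            dA = dZ @ self.W[l].T
        if self.batch_norm:
            return gW + gb + ggamma + gbeta
        return gW + gb


class Adam:
    """Standard Adam optimizer over a list of parameter arrays (in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
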