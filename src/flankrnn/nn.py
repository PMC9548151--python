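"""Minimal numpy neural-network core: bidirectional GRU, dense head, Adam.

Implements exactly what the sequence classifiers need: stacked
bidirectional gated-recurrent-unit layers over a loci x features window, a
dense stack with inverted dropout, a single sigmoid output unit, binary
cross-entropy, and the Adam optimizer.  Gradients are analytic
(backpropagation through time) and are verified against numerical
differentiation in the test suite.

GRU convention per timestep (sigmoid gates, tanh candidate):

    z_t = sigma(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigma(x_t Wr + h_{t-1} Ur + br)
    hhat = tanh(x_t Wh + (r_t * h_{t-1}) Uh + bh)
    h_t = (1 - z_t) * h_{t-1} + z_t * hhat

All computation is float64.
"""

from __future__ import annotations

import copy
from typing import Callable

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GRUDirection:
    """Single-direction GRU processing (B, T, F) -> (B, T, U)."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.n_in, self.units = n_in, units
        p = {}
        for g in ("z", "r", "h"):
            p[f"W{g}"] = _glorot(rng, n_in, units)
            p[f"U{g}"] = _glorot(rng, units, units)
            p[f"b{g}"] = np.zeros(units)
        self.params = p
        self.grads = {k: np.zeros_like(v) for k, v in p.items()}
        self._cache = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        U = self.units
        p = self.params
        H = np.zeros((B, T, U))
        Z = np.zeros((B, T, U))
        R = np.zeros((B, T, U))
        HH = np.zeros((B, T, U))
        Hprev = np.zeros((B, T, U))
        h = np.zeros((B, U))
        xz = X @ p["Wz"] + p["bz"]
        xr = X @ p["Wr"] + p["br"]
        xh = X @ p["Wh"] + p["bh"]
        for t in range(T):
            Hprev[:, t] = h
            z = sigmoid(xz[:, t] + h @ p["Uz"])
            r = sigmoid(xr[:, t] + h @ p["Ur"])
            hh = np.tanh(xh[:, t] + (r * h) @ p["Uh"])
            h = (1 - z) * h + z * hh
            Z[:, t], R[:, t], HH[:, t], H[:, t] = z, r, hh, h
        self._cache = (X, Z, R, HH, Hprev)
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        X, Z, R, HH, Hprev = self._cache
        B, T, F = X.shape
        p, g = self.params, self.grads
        for k in g:
            g[k].fill(0.0)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, self.units))
        for t in range(T - 1, -1, -1):
            z, r, hh, hprev = Z[:, t], R[:, t], HH[:, t], Hprev[:, t]
            x = X[:, t]
            dh = dH[:, t] + dh_next
            dz = dh * (hh - hprev)
            dhh = dh * z
            dhprev = dh * (1 - z)
            dhpre = dhh * (1 - hh * hh)
            g["Wh"] += x.T @ dhpre
            g["Uh"] += (r * hprev).T @ dhpre
            g["bh"] += dhpre.sum(axis=0)
            drh = dhpre @ p["Uh"].T
            dr = drh * hprev
            dhprev += drh * r
            dzpre = dz * z * (1 - z)
            drpre = dr * r * (1 - r)
            g["Wz"] += x.T @ dzpre
            g["Uz"] += hprev.T @ dzpre
            g["bz"] += dzpre.sum(axis=0)
            g["Wr"] += x.T @ drpre
            g["Ur"] += hprev.T @ drpre
            g["br"] += drpre.sum(axis=0)
            dX[:, t] = dzpre @ p["Wz"].T + drpre @ p["Wr"].T + dhpre @ p["Wh"].T
            dh_next = dhprev + dzpre @ p["Uz"].T + drpre @ p["Ur"].T
        return dX


class BiGRU:
    """Bidirectional GRU; output is the per-locus concatenation (B, T, 2U)."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.fwd = GRUDirection(n_in, units, rng)
        self.bwd = GRUDirection(n_in, units, rng)
        self.units = units

    @property
    def n_out(self) -> int:
        return 2 * self.units

    def forward(self, X: np.ndarray) -> np.ndarray:
        Hf = self.fwd.forward(X)
        Hb = self.bwd.forward(X[:, ::-1])[:, ::-1]
        return np.concatenate([Hf, Hb], axis=2)

    def backward(self, dH: np.ndarray) -> np.ndarray:
        U = self.units
        dXf = self.fwd.backward(dH[:, :, :U])
        dXb = self.bwd.backward(dH[:, ::-1, U:])[:, ::-1]
        return dXf + dXb

    def iter_params(self):
        for name, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k in d.params:
                yield f"{name}/{k}", d.params, d.grads, k


class Dense:
    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool = True
    ):
        self.params = {"W": _glorot(rng, n_in, n_out), "b": np.zeros(n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.relu = relu
        self._cache = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        pre = X @ self.params["W"] + self.params["b"]
        out = np.maximum(pre, 0.0) if self.relu else pre
        self._cache = (X, pre)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        X, pre = self._cache
        if self.relu:
            dout = dout * (pre > 0)
        self.grads["W"][...] = X.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T

    def iter_params(self):
        for k in self.params:
            yield k, self.params, self.grads, k


class Adam:
    """Adam optimizer over a flat {name: array} parameter view."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            gk = grads[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m += (1 - b1) * (gk - m)
            v += (1 - b2) * (gk * gk - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


HEAD_TARGET_CROP = "target_locus_crop"
HEAD_FINAL_LOCUS = "final_locus"


class SequenceClassifier:
    """Stacked bi-GRU over a (T, F) window with a sigmoid head.

    ``head_mode='target_locus_crop'`` keeps only the bidirectional state at
    ``target_index`` (both directions' states at that locus concatenated);
    ``head_mode='final_locus'`` keeps the forward state at the last locus and
    the backward state at the first (the final step of each direction).
    """

    def __init__(
        self,
        seq_len: int,
        n_features: int,
        gru_units: list[int],
        dense_units: list[int],
        head_mode: str,
        target_index: int | None = None,
        dropout: float = 0.0,
        seed: int = 0,
    ):
        if head_mode not in (HEAD_TARGET_CROP, HEAD_FINAL_LOCUS):
            raise ValueError(f"unknown head_mode {head_mode!r}")
        if head_mode == HEAD_TARGET_CROP and target_index is None:
            raise ValueError("target_locus_crop requires a target_index")
        if not gru_units:
            raise ValueError("at least one GRU layer required")
        self.seq_len = seq_len
        self.n_features = n_features
        self.head_mode = head_mode
        self.target_index = target_index
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        self.gru_layers: list[BiGRU] = []
        n_in = n_features
        for u in gru_units:
            self.gru_layers.append(BiGRU(n_in, u, rng))
            n_in = 2 * u
        self.dense_layers: list[Dense] = []
        for u in dense_units:
            self.dense_layers.append(Dense(n_in, u, rng, relu=True))
            n_in = u
        self.out_layer = Dense(n_in, 1, rng, relu=False)
        self._drop_masks: list[np.ndarray] = []

    # -- parameter plumbing ------------------------------------------------
    def _param_entries(self):
        for i, l in enumerate(self.gru_layers):
            for sub, params, grads, k in l.iter_params():
                yield f"gru{i}/{sub}", params, grads, k
        for i, l in enumerate(self.dense_layers):
            for sub, params, grads, k in l.iter_params():
                yield f"dense{i}/{sub}", params, grads, k
        for sub, params, grads, k in self.out_layer.iter_params():
            yield f"out/{sub}", params, grads, k

    def parameters(self) -> dict[str, np.ndarray]:
        return {name: params[k] for name, params, _, k in self._param_entries()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {name: grads[k] for name, _, grads, k in self._param_entries()}

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, params, _, k in self._param_entries():
            params[k][...] = state[name]

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    # -- forward / backward ------------------------------------------------
    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.seq_len or X.shape[2] != self.n_features:
            raise ValueError(
                f"expected input of shape (n, {self.seq_len}, {self.n_features}), "
                f"got {X.shape}"
            )
        return X

    def _head(self, H: np.ndarray) -> np.ndarray:
        U = self.gru_layers[-1].units
        if self.head_mode == HEAD_TARGET_CROP:
            return H[:, self.target_index, :]
        return np.concatenate([H[:, -1, :U], H[:, 0, U:]], axis=1)

    def forward(
        self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        X = self._check_input(X)
        H = X
        for l in self.gru_layers:
            H = l.forward(H)
        h = self._head(H)
        self._drop_masks = []
        for l in self.dense_layers:
            h = l.forward(h)
            if train and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * mask
                self._drop_masks.append(mask)
        logit = self.out_layer.forward(h)[:, 0]
        return sigmoid(logit)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False)

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean BCE and analytic gradients for one batch."""
        X = self._check_input(X)
        y = np.asarray(y, dtype=float)
        p = self.forward(X, train=self.dropout > 0, rng=rng)
        loss = bce_loss(p, y)
        B = X.shape[0]
        # d(BCE)/d(logit) = (p - y) / B  (sigmoid + BCE simplification)
        dlogit = (p - y)[:, None] / B
        dh = self.out_layer.backward(dlogit)
        for i in range(len(self.dense_layers) - 1, -1, -1):
            if self._drop_masks:
                dh = dh * self._drop_masks[i]
            dh = self.dense_layers[i].backward(dh)
        T = self.seq_len
        U = self.gru_layers[-1].units
        dH = np.zeros((B, T, 2 * U))
        if self.head_mode == HEAD_TARGET_CROP:
            dH[:, self.target_index, :] = dh
        else:
            dH[:, -1, :U] = dh[:, :U]
            dH[:, 0, U:] = dh[:, U:]
        for l in reversed(self.gru_layers):
            dH = l.backward(dH)
        return loss, self.gradients()


class FeedForwardClassifier:
    """Dense-only classifier over the target locus feature vector alone."""

    def __init__(
        self,
        n_features: int,
        dense_units: list[int],
        dropout: float = 0.0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.dropout = float(dropout)
        self.dense_layers: list[Dense] = []
        n_in = n_features
        for u in dense_units:
            self.dense_layers.append(Dense(n_in, u, rng, relu=True))
            n_in = u
        self.out_layer = Dense(n_in, 1, rng, relu=False)
        self._drop_masks: list[np.ndarray] = []

    def _param_entries(self):
        for i, l in enumerate(self.dense_layers):
            for sub, params, grads, k in l.iter_params():
                yield f"dense{i}/{sub}", params, grads, k
        for sub, params, grads, k in self.out_layer.iter_params():
            yield f"out/{sub}", params, grads, k

    def parameters(self) -> dict[str, np.ndarray]:
        return {name: params[k] for name, params, _, k in self._param_entries()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {name: grads[k] for name, _, grads, k in self._param_entries()}

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, params, _, k in self._param_entries():
            params[k][...] = state[name]

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None]
        if X.ndim == 3 and X.shape[1] == 1:
            X = X[:, 0, :]
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected input of shape (n, {self.n_features}), got {X.shape}"
            )
        return X

    def forward(
        self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        h = self._check_input(X)
        self._drop_masks = []
        for l in self.dense_layers:
            h = l.forward(h)
            if train and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * mask
                self._drop_masks.append(mask)
        return sigmoid(self.out_layer.forward(h)[:, 0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False)

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        X = self._check_input(X)
        y = np.asarray(y, dtype=float)
        p = self.forward(X, train=self.dropout > 0, rng=rng)
        loss = bce_loss(p, y)
        dlogit = (p - y)[:, None] / X.shape[0]
        dh = self.out_layer.backward(dlogit)
        for i in range(len(self.dense_layers) - 1, -1, -1):
            if self._drop_masks:
                dh = dh * self._drop_masks[i]
            dh = self.dense_layers[i].backward(dh)
        return loss, self.gradients()
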