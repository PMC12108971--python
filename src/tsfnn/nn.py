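"""Minimal feed-forward neural network core in numpy.

Implements exactly what the fusion classifier needs: dense layers, ReLU,
batch normalization with mini-batch statistics in training and exponential
running statistics at inference, a sigmoid/binary-cross-entropy output
handled in logit space for numerical stability, Adam, and a mini-batch
training loop.  All randomness (weight init, shuffling) flows from an
explicit numpy Generator so every run is reproducible.

Networks produce a single logit; probabilities are ``sigmoid(logit)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    # stable piecewise form
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean binary cross-entropy computed from logits (log-sum-exp form)."""
    z = logits.ravel()
    y = y.ravel()
    # log(1 + e^-|z|) + max(z,0) - z*y
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    if weights is not None:
        return float(np.sum(loss * weights) / np.sum(weights))
    return float(np.mean(loss))


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine transform with He-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def __init__(self) -> None:
        self.params = []
        self.grads = []
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return grad * self._mask


class BatchNorm(Layer):
    """Normalize each node by mini-batch mean/std, then scale and shift.

    During training the layer uses the statistics of the current mini-batch
    and updates exponential running estimates; at inference the running
    estimates are used, so prediction is a pure function of the weights.
    """

    def __init__(self, n: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            x_hat = (x - mean) * inv_std
            self._cache = (x_hat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            x_hat = (x - self.running_mean) * inv_std
        return self.gamma * x_hat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x_hat, inv_std = self._cache
        m = grad.shape[0]
        self.grads[0][...] = np.sum(grad * x_hat, axis=0)
        self.grads[1][...] = grad.sum(axis=0)
        g = grad * self.gamma
        return inv_std / m * (m * g - g.sum(axis=0) - x_hat * np.sum(g * x_hat, axis=0))


class Sequential:
    """An ordered stack of layers ending in a single-logit output."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def hidden_block(n_in: int, n_out: int, rng: np.random.Generator, batch_norm: bool) -> list[Layer]:
    """Dense -> (BatchNorm) -> ReLU, the repeated unit of every branch."""
    layers: list[Layer] = [Dense(n_in, n_out, rng)]
    if batch_norm:
        layers.append(BatchNorm(n_out))
    layers.append(ReLU())
    return layers


class TwoBranchNet:
    """Two input branches whose outputs are concatenated into a head.

    With a hidden fusion layer in the head this is the three-stage fusion
    topology; with a bare output layer it is the two-way baseline.  A
    single-branch network is expressed by a Sequential instead.
    """

    def __init__(self, num_branch: Sequential, cat_branch: Sequential, head: Sequential):
        self.num_branch = num_branch
        self.cat_branch = cat_branch
        self.head = head
        self._split: int | None = None

    def forward(self, x_num: np.ndarray, x_cat: np.ndarray, training: bool = False) -> np.ndarray:
        h_num = self.num_branch.forward(x_num, training)
        h_cat = self.cat_branch.forward(x_cat, training)
        self._split = h_num.shape[1]
        return self.head.forward(np.concatenate([h_num, h_cat], axis=1), training)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        assert self._split is not None
        self.num_branch.backward(g[:, : self._split])
        self.cat_branch.backward(g[:, self._split :])

    def parameters(self) -> list[np.ndarray]:
        return self.num_branch.parameters() + self.cat_branch.parameters() + self.head.parameters()

    def gradients(self) -> list[np.ndarray]:
        return self.num_branch.gradients() + self.cat_branch.gradients() + self.head.gradients()


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.grads = grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainLog:
    loss_per_epoch: list[float] = field(default_factory=list)


class TrainingDiverged(RuntimeError):
    pass


def train_network(
    net,
    inputs: tuple[np.ndarray, ...],
    y: np.ndarray,
    *,
    epochs: int,
    learning_rate: float,
    batch_size: int,
    rng: np.random.Generator,
    sample_weights: np.ndarray | None = None,
) -> TrainLog:
    """Mini-batch BCE training of a Sequential (1 input) or TwoBranchNet (2).

    Returns the per-epoch mean mini-batch loss.  Aborts with a diagnostic if
    the loss becomes non-finite.
    """
    n = y.shape[0]
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    opt = Adam(net.parameters(), net.gradients(), lr=learning_rate)
    log = TrainLog()
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch_inputs = tuple(x[idx] for x in inputs)
            yb = y[idx]
            wb = sample_weights[idx] if sample_weights is not None else None
            logits = net.forward(*batch_inputs, training=True)
            loss = bce_with_logits(logits, yb, wb)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss {loss} at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            # d(mean BCE)/d(logit) = (sigmoid(z) - y) / m  (weighted accordingly)
            p = sigmoid(logits)
            if wb is not None:
                grad = (p - yb) * wb.reshape(-1, 1) / np.sum(wb)
            else:
                grad = (p - yb) / yb.shape[0]
            net.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        log.loss_per_epoch.append(float(np.mean(epoch_losses)))
    return log


# ---------------------------------------------------------------------------
# Weight (de)serialization: nested lists, JSON-friendly, text-only.

def get_state(net) -> dict:
    state: dict = {"params": [p.tolist() for p in net.parameters()], "running": []}
    layers = (
        net.layers
        if isinstance(net, Sequential)
        else net.num_branch.layers + net.cat_branch.layers + net.head.layers
    )
    for layer in layers:
        if isinstance(layer, BatchNorm):
            state["running"].append(
                {"mean": layer.running_mean.tolist(), "var": layer.running_var.tolist()}
            )
    return state


def set_state(net, state: dict) -> None:
    for p, saved in zip(net.parameters(), state["params"], strict=True):
        p[...] = np.asarray(saved, dtype=float)
    layers = (
        net.layers
        if isinstance(net, Sequential)
        else net.num_branch.layers + net.cat_branch.layers + net.head.layers
    )
    bn_layers = [l for l in layers if isinstance(l, BatchNorm)]
    for layer, saved in zip(bn_layers, state["running"], strict=True):
        layer.running_mean = np.asarray(saved["mean"], dtype=float)
        layer.running_var = np.asarray(saved["var"], dtype=float)
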