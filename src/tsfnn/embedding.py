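"""Embedding layer for the categorical items.

A one-hidden-layer network (input -> hidden -> 1 sigmoid output) is
pre-trained on the fracture label; its output node is then removed, so the
hidden activations become a dense real-valued representation — by default a
20-dimensional vector — of the ten ordinal-encoded categorical items.

Two input representations of a 10-code vector are supported:

* ``scaled_ordinal`` (default): each global code min-max scaled to [0, 1]
  over the full code range 1..30 — the literal reading of "encodes 10
  ordinal codes".
* ``one_hot``: a 30-length indicator vector with ten ones, one per selected
  option.

Stripping is exact: for every input, the embedding equals the hidden
activations of the un-stripped pre-training network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Dense, ReLU, Sequential, sigmoid, train_network


@dataclass
class EmbeddingConfig:
    hidden_width: int = 20
    input_representation: str = "scaled_ordinal"  # or "one_hot"
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        if self.input_representation not in ("scaled_ordinal", "one_hot"):
            raise ValueError(f"unknown representation {self.input_representation!r}")


def represent_codes(codes: np.ndarray, representation: str, max_code: int) -> np.ndarray:
    """Turn an (n, 10) integer code matrix into the network input matrix."""
    codes = np.atleast_2d(np.asarray(codes, dtype=int))
    if np.any(codes < 1) or np.any(codes > max_code):
        raise ValueError(f"codes must lie in 1..{max_code}")
    if representation == "scaled_ordinal":
        if max_code == 1:
            return np.zeros_like(codes, dtype=float)
        return (codes - 1) / (max_code - 1)
    out = np.zeros((codes.shape[0], max_code), dtype=float)
    rows = np.repeat(np.arange(codes.shape[0]), codes.shape[1])
    out[rows, codes.ravel() - 1] = 1.0
    return out


@dataclass
class EmbeddingLayer:
    """The stripped pre-training network: input transform + one hidden layer."""

    weights: np.ndarray  # (d_in, hidden_width)
    biases: np.ndarray  # (hidden_width,)
    input_representation: str
    max_code: int
    activation: str = "relu"
    pretrain_loss: list[float] = field(default_factory=list)

    @property
    def output_dim(self) -> int:
        return self.weights.shape[1]

    def transform(self, codes: np.ndarray) -> np.ndarray:
        """Map an (n, 10) code matrix to (n, output_dim) hidden activations."""
        x = represent_codes(codes, self.input_representation, self.max_code)
        return np.maximum(x @ self.weights + self.biases, 0.0)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "input_representation": self.input_representation,
            "max_code": self.max_code,
            "activation": self.activation,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EmbeddingLayer":
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            biases=np.asarray(payload["biases"], dtype=float),
            input_representation=payload["input_representation"],
            max_code=int(payload["max_code"]),
            activation=payload.get("activation", "relu"),
        )


def pretrain_embedding(
    encoded_records: np.ndarray,
    labels: np.ndarray,
    config: EmbeddingConfig | None = None,
    *,
    max_code: int = 30,
    return_network: bool = False,
):
    """Pre-train the one-hidden-layer network and strip its output node.

    Requires at least two records with both classes present; the returned
    layer is deterministic for a fixed config seed.
    """
    config = config or EmbeddingConfig()
    codes = np.atleast_2d(np.asarray(encoded_records, dtype=int))
    y = np.asarray(labels, dtype=int)
    if codes.shape[0] < 2:
        raise ValueError("pre-training needs at least 2 records")
    if len(set(y.tolist())) < 2:
        raise ValueError("pre-training needs both classes present")

    x = represent_codes(codes, config.input_representation, max_code)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    net = Sequential(
        [
            Dense(x.shape[1], config.hidden_width, rng),
            ReLU(),
            Dense(config.hidden_width, 1, rng),
        ]
    )
    log = train_network(
        net,
        (x,),
        y,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        rng=rng,
    )
    dense = net.layers[0]
    layer = EmbeddingLayer(
        weights=dense.W.copy(),
        biases=dense.b.copy(),
        input_representation=config.input_representation,
        max_code=max_code,
        pretrain_loss=log.loss_per_epoch,
    )
    if return_network:
        return layer, net
    return layer


def embed(encoded_record: np.ndarray, layer: EmbeddingLayer) -> np.ndarray:
    """Embed a single 10-code record as a length-``output_dim`` real vector."""
    codes = np.asarray(encoded_record, dtype=int)
    if codes.ndim != 1:
        raise ValueError("embed expects a single record (1-D code vector)")
    return layer.transform(codes[None, :])[0]


def pretrain_train_accuracy(net: Sequential, x: np.ndarray, y: np.ndarray) -> float:
    """Training accuracy of the un-stripped pre-training network."""
    p = sigmoid(net.forward(x, training=False)).ravel()
    return float(np.mean((p >= 0.5).astype(int) == np.asarray(y, dtype=int)))
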