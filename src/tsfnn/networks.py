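"""The five classifier architectures and their training/prediction.

* ``ann``  — plain multilayer perceptron on the concatenation of the 7
  normalized numerical items and the 10 ordinal codes scaled to [0, 1]
  (input width 17).
* ``nnn``  — numerical branch alone: 7 normalized items -> hidden -> output.
* ``cnn``  — categorical branch alone (not convolutional): the embedded
  20-vector (or the 10 scaled codes when the embedding is disabled)
  -> hidden -> output.
* ``two_way`` — both branches, their hidden outputs concatenated directly
  into the output node: no fusion sub-network.
* ``tsfnn``  — three-stage fusion: numerical branch, categorical branch,
  and a fusion sub-network (concatenation -> hidden -> output) on top.
  With batch normalization enabled this is the headline configuration.

Default hidden widths (branches 16, fusion 16, plain ANN 32) give the
two-way and fusion networks a comparable number of hidden nodes so their
comparison isolates the fusion stage.  Batch normalization, when enabled,
is inserted after each hidden linear transform and before its activation.

Training is end-to-end after the embedding has been pre-trained (the
embedding stays frozen unless ``fine_tune_embedding``); an optional
``staged_training`` mode instead pre-trains each branch as a standalone
classifier, freezes both, and trains only the fusion head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .embedding import EmbeddingConfig, EmbeddingLayer, pretrain_embedding, represent_codes
from .preprocess import (
    NormalizationParams,
    OrdinalCodebook,
    build_codebook,
    encode_categorical,
    encode_dataset,
    fit_minmax,
    normalize_numeric,
)
from .schema import ClinicalRecord, Dataset

ARCHITECTURES = ("ann", "nnn", "cnn", "two_way", "tsfnn")


@dataclass
class ModelSpec:
    """Architecture choice plus every knob needed to reproduce a training run."""

    architecture: str = "tsfnn"
    num_hidden: int = 16  # numerical-branch hidden width
    cat_hidden: int = 16  # categorical-branch hidden width
    fusion_hidden: int = 16  # fusion sub-network hidden width (tsfnn only)
    ann_hidden: int = 32  # plain-ANN hidden width
    use_batch_norm: bool = True
    use_embedding: bool = True  # cnn / two_way / tsfnn only
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    fine_tune_embedding: bool = False
    staged_training: bool = False
    activation: str = "relu"
    epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0
    decision_threshold: float = 0.5
    class_weight: bool = False
    normalization_mode: str = "standard"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; pick from {ARCHITECTURES}")
        if isinstance(self.embedding, dict):
            self.embedding = EmbeddingConfig(**self.embedding)

    def with_seed(self, seed: int) -> "ModelSpec":
        payload = asdict(self)
        payload["seed"] = seed
        payload["embedding"] = dict(payload["embedding"], seed=seed)
        return ModelSpec(**payload)

    def hidden_node_count(self) -> int:
        """Total hidden nodes, used to check branch-count parity of baselines."""
        if self.architecture == "ann":
            return self.ann_hidden
        if self.architecture == "nnn":
            return self.num_hidden
        if self.architecture == "cnn":
            return self.cat_hidden
        if self.architecture == "two_way":
            return self.num_hidden + self.cat_hidden
        return self.num_hidden + self.cat_hidden + self.fusion_hidden


def build_model(spec: ModelSpec, n_numeric: int = 7, rng: np.random.Generator | None = None):
    """Instantiate the untrained network for ``spec`` with seeded init."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    bn = spec.use_batch_norm
    if spec.architecture == "ann":
        n_in = n_numeric + 10
        return nn.Sequential(
            nn.hidden_block(n_in, spec.ann_hidden, rng, bn) + [nn.Dense(spec.ann_hidden, 1, rng)]
        )
    if spec.architecture == "nnn":
        return nn.Sequential(
            nn.hidden_block(n_numeric, spec.num_hidden, rng, bn)
            + [nn.Dense(spec.num_hidden, 1, rng)]
        )
    cat_dim = spec.embedding.hidden_width if spec.use_embedding else 10
    if spec.architecture == "cnn":
        return nn.Sequential(
            nn.hidden_block(cat_dim, spec.cat_hidden, rng, bn) + [nn.Dense(spec.cat_hidden, 1, rng)]
        )
    num_branch = nn.Sequential(nn.hidden_block(n_numeric, spec.num_hidden, rng, bn))
    cat_branch = nn.Sequential(nn.hidden_block(cat_dim, spec.cat_hidden, rng, bn))
    joint = spec.num_hidden + spec.cat_hidden
    if spec.architecture == "two_way":
        head = nn.Sequential([nn.Dense(joint, 1, rng)])
    else:  # tsfnn
        head = nn.Sequential(
            nn.hidden_block(joint, spec.fusion_hidden, rng, bn)
            + [nn.Dense(spec.fusion_hidden, 1, rng)]
        )
    return nn.TwoBranchNet(num_branch, cat_branch, head)


@dataclass
class TrainedModel:
    """A trained classifier bundling the net and its preprocessing artifacts."""

    spec: ModelSpec
    norm_params: NormalizationParams
    codebook: OrdinalCodebook
    embedding_layer: Optional[EmbeddingLayer]
    net: object
    train_log: nn.TrainLog

    def _features(self, record: ClinicalRecord) -> tuple[np.ndarray, ...]:
        codes = encode_categorical(record, self.codebook)
        x_num = np.array(
            [
                [
                    _apply(record.numerical_values[i], i, self.norm_params)
                    for i in self.norm_params.item_ids
                ]
            ]
        )
        return _assemble_inputs(self.spec, x_num, codes[None, :], self.embedding_layer,
                                self.codebook.max_code)

    def predict_proba(self, record: ClinicalRecord) -> float:
        logits = self.net.forward(*self._features(record), training=False)
        return float(nn.sigmoid(logits)[0, 0])

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "tsfnn-model-v1",
            "spec": _spec_to_dict(self.spec),
            "norm_params": {
                "mode": self.norm_params.mode,
                "min_value": {str(k): v for k, v in self.norm_params.min_value.items()},
                "max_value": {str(k): v for k, v in self.norm_params.max_value.items()},
            },
            "codebook": {
                "codes": [
                    {"item_id": i, "option": o, "code": c}
                    for (i, o), c in sorted(self.codebook.codes.items(), key=lambda kv: kv[1])
                ],
                "item_ids": self.codebook.item_ids,
            },
            "embedding": self.embedding_layer.to_dict() if self.embedding_layer else None,
            "net_state": nn.get_state(self.net),
            "loss_per_epoch": self.train_log.loss_per_epoch,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "tsfnn-model-v1":
            raise ValueError("not a recognized model file")
        spec = ModelSpec(**payload["spec"])
        norm = NormalizationParams(
            min_value={int(k): float(v) for k, v in payload["norm_params"]["min_value"].items()},
            max_value={int(k): float(v) for k, v in payload["norm_params"]["max_value"].items()},
            mode=payload["norm_params"]["mode"],
        )
        codebook = OrdinalCodebook(
            {(int(e["item_id"]), e["option"]): int(e["code"]) for e in payload["codebook"]["codes"]},
            [int(i) for i in payload["codebook"]["item_ids"]],
        )
        emb = EmbeddingLayer.from_dict(payload["embedding"]) if payload["embedding"] else None
        net = build_model(spec, n_numeric=len(norm.item_ids))
        if emb is not None and spec.fine_tune_embedding:
            net = _prepend_embedding(net, emb, spec)
        nn.set_state(net, payload["net_state"])
        return cls(spec, norm, codebook, emb, net, nn.TrainLog(payload["loss_per_epoch"]))


def _spec_to_dict(spec: ModelSpec) -> dict:
    payload = asdict(spec)
    return payload


def _apply(value, item_id, params):
    from .preprocess import apply_minmax

    return apply_minmax(value, item_id, params)


def _scaled_codes(codes: np.ndarray, max_code: int) -> np.ndarray:
    return (np.atleast_2d(codes) - 1) / (max_code - 1)


def _assemble_inputs(
    spec: ModelSpec,
    x_num: np.ndarray,
    codes: np.ndarray,
    embedding_layer: Optional[EmbeddingLayer],
    max_code: int,
) -> tuple[np.ndarray, ...]:
    """Compose the network input(s) for an architecture from raw features."""
    if spec.architecture == "ann":
        return (np.concatenate([x_num, _scaled_codes(codes, max_code)], axis=1),)
    if spec.architecture == "nnn":
        return (x_num,)
    if spec.use_embedding:
        if embedding_layer is None:
            raise ValueError("spec requests the embedding but none was trained")
        if spec.fine_tune_embedding:
            x_cat = represent_codes(codes, embedding_layer.input_representation, max_code)
        else:
            x_cat = embedding_layer.transform(codes)
    else:
        x_cat = _scaled_codes(codes, max_code)
    if spec.architecture == "cnn":
        return (x_cat,)
    return (x_num, x_cat)


def _prepend_embedding(net, layer: EmbeddingLayer, spec: ModelSpec):
    """Make the embedding trainable by grafting it onto the categorical path."""
    rng = np.random.default_rng(0)
    d_in, d_out = layer.weights.shape
    dense = nn.Dense(d_in, d_out, rng)
    dense.W[...] = layer.weights
    dense.b[...] = layer.biases
    prefix = [dense, nn.ReLU()]
    if isinstance(net, nn.Sequential):  # cnn
        return nn.Sequential(prefix + net.layers)
    net.cat_branch = nn.Sequential(prefix + net.cat_branch.layers)
    return net


def train(
    dataset: Dataset,
    spec: ModelSpec,
    *,
    artifacts: tuple[NormalizationParams, OrdinalCodebook, Optional[EmbeddingLayer]] | None = None,
) -> TrainedModel:
    """Fit preprocessing, pre-train the embedding if used, train the network.

    All fitting uses the supplied dataset only, so calling this inside a
    cross-validation fold never leaks the held-out record.  Pre-fitted
    ``artifacts`` may be supplied to evaluate a global-fit protocol instead.
    """
    labels = np.array(dataset.labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both classes present")

    if artifacts is not None:
        norm_params, codebook, embedding_layer = artifacts
    else:
        norm_params = fit_minmax(dataset, mode=spec.normalization_mode)
        codebook = build_codebook(dataset.schema)
        embedding_layer = None

    codes = encode_dataset(dataset, codebook)
    needs_embedding = spec.use_embedding and spec.architecture in ("cnn", "two_way", "tsfnn")
    if needs_embedding and embedding_layer is None:
        embedding_layer = pretrain_embedding(
            codes, labels, spec.embedding, max_code=codebook.max_code
        )
    x_num = normalize_numeric(dataset, norm_params)
    inputs = _assemble_inputs(spec, x_num, codes, embedding_layer if needs_embedding else None,
                              codebook.max_code)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    net = build_model(spec, n_numeric=x_num.shape[1], rng=rng)
    if needs_embedding and spec.fine_tune_embedding:
        net = _prepend_embedding(net, embedding_layer, spec)

    sample_weights = None
    if spec.class_weight:
        # inverse-frequency weights, mean 1
        freq = np.bincount(labels, minlength=2) / len(labels)
        w = np.where(labels == 1, 1.0 / (2 * freq[1]), 1.0 / (2 * freq[0]))
        sample_weights = w

    if spec.staged_training and spec.architecture in ("two_way", "tsfnn"):
        log = _train_staged(net, inputs, labels, spec, rng, sample_weights)
    else:
        log = nn.train_network(
            net,
            inputs,
            labels,
            epochs=spec.epochs,
            learning_rate=spec.learning_rate,
            batch_size=spec.batch_size,
            rng=rng,
            sample_weights=sample_weights,
        )
    emb_out = embedding_layer if needs_embedding else None
    return TrainedModel(spec, norm_params, codebook, emb_out, net, log)


def _train_staged(net: nn.TwoBranchNet, inputs, labels, spec: ModelSpec, rng, sample_weights):
    """Branch-wise pre-training followed by fusion-head-only training."""
    x_num, x_cat = inputs
    logs = []
    for branch, x in ((net.num_branch, x_num), (net.cat_branch, x_cat)):
        probe = nn.Sequential(branch.layers + [nn.Dense(branch.layers[0].W.shape[1], 1, rng)])
        logs.append(
            nn.train_network(
                probe, (x,), labels,
                epochs=spec.epochs, learning_rate=spec.learning_rate,
                batch_size=spec.batch_size, rng=rng, sample_weights=sample_weights,
            )
        )
    # freeze branches: train only the head on their (fixed) activations
    h = np.concatenate(
        [net.num_branch.forward(x_num, training=False), net.cat_branch.forward(x_cat, training=False)],
        axis=1,
    )
    head_log = nn.train_network(
        net.head, (h,), labels,
        epochs=spec.epochs, learning_rate=spec.learning_rate,
        batch_size=spec.batch_size, rng=rng, sample_weights=sample_weights,
    )
    return nn.TrainLog(head_log.loss_per_epoch)


def predict(trained: TrainedModel, record: ClinicalRecord) -> tuple[float, int]:
    """Probability of fracture and thresholded label (tie goes positive).

    The record is checked against the model's own vocabulary: unknown
    categorical options or missing numerical items raise.
    """
    missing = [i for i in trained.norm_params.item_ids if i not in record.numerical_values]
    if missing:
        raise ValueError(f"record is missing numerical item(s) {missing}")
    prob = trained.predict_proba(record)
    label = int(prob >= trained.spec.decision_threshold)
    return prob, label


def training_accuracy(trained: TrainedModel, dataset: Dataset) -> float:
    preds = [predict(trained, r)[1] for r in dataset.records]
    return float(np.mean(np.array(preds) == np.array(dataset.labels)))
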