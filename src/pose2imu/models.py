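"""Identification classifiers: three 1-D CNN families and their training loop.

* ``vanilla_cnn`` — three conv blocks (64/128/128 filters, kernels 7/5/3,
  each ReLU + max-pool 2) → global average pooling → softmax head.  Consumes
  one stacked array, canonically 128 x 6.
* ``attention_cnn`` — the same trunk with the global pool replaced by additive
  temporal attention pooling.
* ``multi_input_cnn`` — two branches with identical trunks (32/64/64 filters,
  kernels 7/5/3) and therefore identical kernel counts, so the two modalities
  are weighted equally at the decision stage; branch embeddings are
  concatenated into a 128-unit dense layer before the softmax head.  Consumes
  a pair of branch arrays, canonically 100 x 3 each.

Training follows the reference protocol: categorical cross-entropy, Adam at
learning rate 0.01, a fixed epoch budget (default 300) with no early
stopping, and repetition over independently seeded weight initialisations to
average out initialisation luck.  All randomness derives from explicit seeds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .datasets_io import FeatureTensorSet

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict_scores",
]

MODEL_FAMILIES = ("vanilla_cnn", "attention_cnn", "multi_input_cnn")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description.

    ``input_shapes`` holds one ``(length, channels)`` tuple for the stacked
    families and exactly two for ``multi_input_cnn`` (branches must agree in
    kernel counts by construction).  Filter/kernel choices are overridable.
    """

    family: str
    input_shapes: tuple[tuple[int, int], ...]
    n_classes: int
    seed: int = 0
    trunk_filters: tuple[int, int, int] = (64, 128, 128)
    branch_filters: tuple[int, int, int] = (32, 64, 64)
    kernels: tuple[int, int, int] = (7, 5, 3)
    dense_units: int = 128

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; pick from {MODEL_FAMILIES}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.family == "multi_input_cnn":
            if len(self.input_shapes) != 2:
                raise ValueError("multi_input_cnn requires exactly 2 branches")
        elif len(self.input_shapes) != 1:
            raise ValueError(f"{self.family} takes a single stacked input")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol (defaults follow the reference setup)."""

    learning_rate: float = 0.01
    epochs: int = 300
    batch_size: int = 32
    repetitions: int = 20

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size, self.repetitions) <= 0:
            raise ValueError("all training settings must be positive")


def _trunk(c_in: int, filters, kernels, rng) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    prev = c_in
    for f, k in zip(filters, kernels):
        layers += [nn.Conv1D(prev, f, k, rng), nn.ReLU(), nn.MaxPool1D()]
        prev = f
    return layers


class _StackedCNN:
    """Single-input trunk + pooling + linear head; emits logits."""

    def __init__(self, spec: ModelSpec, pooling: str):
        rng = np.random.default_rng(spec.seed)
        c_in = spec.input_shapes[0][1]
        layers = _trunk(c_in, spec.trunk_filters, spec.kernels, rng)
        top = spec.trunk_filters[-1]
        if pooling == "attention":
            self.pool = nn.AttentionPool(top, rng)
        else:
            self.pool = nn.GlobalAvgPool()
        layers += [self.pool, nn.Dense(top, spec.n_classes, rng)]
        self.net = nn.Sequential(layers)
        self.spec = spec

    def forward(self, x):
        return self.net.forward(self._unwrap(x))

    def backward(self, dy):
        return self.net.backward(dy)

    def parameters(self):
        return self.net.parameters()

    @staticmethod
    def _unwrap(x):
        return x[0] if isinstance(x, (list, tuple)) else x

    def attention_weights(self, x):
        if not isinstance(self.pool, nn.AttentionPool):
            raise AttributeError("model has no attention pooling")
        x = self._unwrap(x)
        for layer in self.net.layers:
            if layer is self.pool:
                break
            x = layer.forward(x)
        return self.pool.weights(x)


class _MultiInputCNN:
    """Two equal-kernel branches → concat → dense head; emits logits."""

    def __init__(self, spec: ModelSpec):
        rng = np.random.default_rng(spec.seed)
        self.branches = [
            nn.Sequential(
                _trunk(shape[1], spec.branch_filters, spec.kernels, rng)
                + [nn.GlobalAvgPool()]
            )
            for shape in spec.input_shapes
        ]
        emb = spec.branch_filters[-1] * len(self.branches)
        self.head = nn.Sequential(
            [
                nn.Dense(emb, spec.dense_units, rng),
                nn.ReLU(),
                nn.Dense(spec.dense_units, spec.n_classes, rng),
            ]
        )
        self.spec = spec

    def forward(self, xs):
        if not isinstance(xs, (list, tuple)) or len(xs) != len(self.branches):
            raise ValueError(f"expected {len(self.branches)} branch arrays")
        self._embs = [b.forward(x) for b, x in zip(self.branches, xs)]
        return self.head.forward(np.concatenate(self._embs, axis=1))

    def backward(self, dy):
        demb = self.head.backward(dy)
        splits = np.cumsum([e.shape[1] for e in self._embs])[:-1]
        return [
            b.backward(d) for b, d in zip(self.branches, np.split(demb, splits, axis=1))
        ]

    def parameters(self):
        out = []
        for b in self.branches:
            out.extend(b.parameters())
        out.extend(self.head.parameters())
        return out

    def branch_param_counts(self):
        return [sum(p.size for p, _ in b.parameters()) for b in self.branches]


def build_model(spec: ModelSpec):
    """Instantiate an untrained network from a spec (weights seeded)."""
    if spec.family == "vanilla_cnn":
        return _StackedCNN(spec, pooling="average")
    if spec.family == "attention_cnn":
        return _StackedCNN(spec, pooling="attention")
    return _MultiInputCNN(spec)


@dataclass
class TrainedModel:
    """A fitted network with its optimisation history and provenance."""

    model: object
    spec: ModelSpec
    config: TrainConfig
    seed: int
    history: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.history[-1]


def _as_branch_list(features) -> tuple[list[np.ndarray], np.ndarray]:
    if isinstance(features, FeatureTensorSet):
        return features.arrays, features.labels
    xs, y = features
    if not isinstance(xs, (list, tuple)):
        xs = [xs]
    return list(xs), np.asarray(y)


def train(model, features, cfg: TrainConfig, seed: int) -> TrainedModel:
    """Run the full epoch budget of Adam + cross-entropy on ``features``.

    No early stopping; shuffling is driven solely by ``seed``, so training is
    reproducible and invariant to the incoming trial order.  Aborts with a
    diagnostic if the loss turns non-finite (e.g. a divergent learning rate).
    """
    xs, y = _as_branch_list(features)
    n = len(y)
    if n == 0:
        raise ValueError("no training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 classes")

    # canonical content-based order first, so the incoming row order cannot matter
    digests = np.array(
        [
            int.from_bytes(
                hashlib.blake2b(
                    b"".join(x[i].tobytes() for x in xs), digest_size=8
                ).digest(),
                "big",
            )
            for i in range(n)
        ],
        dtype=np.uint64,
    )
    base = np.lexsort((digests, y))
    xs = [x[base] for x in xs]
    y = y[base]

    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [x[idx] for x in xs]
            logits = model.forward(batch if len(batch) > 1 else batch[0])
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}; "
                    "lower the learning rate"
                )
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedModel(model, model.spec, cfg, seed, history)


def predict_scores(trained, features) -> np.ndarray:
    """Class-probability rows (softmax over logits); rows sum to 1."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    if isinstance(features, FeatureTensorSet):
        xs = features.arrays
    elif isinstance(features, (list, tuple)):
        xs = list(features)
    else:
        xs = [features]
    logits = model.forward(xs if len(xs) > 1 else xs[0])
    return nn.softmax(logits)
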