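"""Residue classifiers: build, train, and apply 3D-CNN models.

Three architectures are registered out of the box:

``timed``
    Convolutional blocks (two 3x3x3 convolutions each, ELU) with spatial
    dropout after every block, then a 1x1x1 convolution to 20 channels and
    global average pooling.  There is no fully connected layer anywhere:
    the global-average-pooling head preserves the spatial interpretation of
    the final feature maps, and spatial dropout drops whole channels so the
    network cannot rely on any single feature map.

``prodconn_like``
    Convolutional blocks followed by flatten + dense hidden layer(s) and a
    dense 20-way output — the classic flatten-dense head.

``densenet3d``
    Densely connected 3D blocks (concatenative skips) with a
    global-average-pooling head.

All models map a batch of voxel frames ``(B, V, V, V, C)`` to a batch of
20-class probability rows.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .constants import AA_ORDER, UNKNOWN_LABEL
from .dataset import FrameDataset, balanced_epoch_indices
from .errors import ConfigError
from .structure_io import BackboneStructure
from .voxelizer import VoxelConfig, voxelise_structure

__all__ = [
    "ModelSpec", "TrainingConfig", "ProbabilityMatrix", "NeuralModel",
    "build_model", "train", "predict_structure", "register_architecture",
    "timed_spec", "prodconn_spec", "densenet_spec",
    "save_model", "load_model",
]


@dataclass
class ModelSpec:
    """Architecture description of a residue classifier."""

    architecture: str
    input_shape: tuple[int, int, int, int]
    conv_blocks: list[tuple] = field(
        default_factory=lambda: [(32, 3, "elu"), (64, 3, "elu"), (128, 3, "elu")])
    spatial_dropout_rate: float = 0.1
    head: str = "global_average_pooling"
    dense_units: list[int] = field(default_factory=lambda: [128])
    n_classes: int = 20
    #: 'same' keeps the full voxel grid through every block; 'valid' lets the
    #: feature maps shrink toward the frame centre, which concentrates the
    #: global-average-pooled evidence for small inputs.
    conv_padding: str = "same"

    def __post_init__(self):
        self.input_shape = tuple(self.input_shape)
        if len(self.input_shape) != 4:
            raise ConfigError("input_shape must be (V, V, V, C)")
        if self.architecture == "timed":
            if self.head != "global_average_pooling":
                raise ConfigError("timed requires a global_average_pooling head")
            if self.spatial_dropout_rate <= 0:
                raise ConfigError("timed requires spatial_dropout_rate > 0")
        if self.architecture == "prodconn_like" and self.head != "flatten_dense":
            raise ConfigError("prodconn_like requires a flatten_dense head")
        if self.n_classes != 20:
            raise ConfigError("residue classifiers are 20-way")
        if self.conv_padding not in ("same", "valid"):
            raise ConfigError("conv_padding must be 'same' or 'valid'")

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "input_shape": list(self.input_shape),
            "conv_blocks": [list(b) for b in self.conv_blocks],
            "spatial_dropout_rate": self.spatial_dropout_rate,
            "head": self.head,
            "dense_units": list(self.dense_units),
            "n_classes": self.n_classes,
            "conv_padding": self.conv_padding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["input_shape"] = tuple(d["input_shape"])
        d["conv_blocks"] = [tuple(b) for b in d["conv_blocks"]]
        return cls(**d)


def timed_spec(input_shape, conv_blocks=None, spatial_dropout_rate=0.1,
               conv_padding="same") -> ModelSpec:
    return ModelSpec(
        architecture="timed", input_shape=input_shape,
        conv_blocks=conv_blocks or [(32, 3, "elu"), (64, 3, "elu"),
                                    (128, 3, "elu")],
        spatial_dropout_rate=spatial_dropout_rate,
        head="global_average_pooling", conv_padding=conv_padding)


def prodconn_spec(input_shape, conv_blocks=None, dense_units=None) -> ModelSpec:
    return ModelSpec(
        architecture="prodconn_like", input_shape=input_shape,
        conv_blocks=conv_blocks or [(16, 3, "elu"), (32, 3, "elu")],
        spatial_dropout_rate=0.0, head="flatten_dense",
        dense_units=dense_units or [128])


def densenet_spec(input_shape, n_blocks: int = 3, growth_rate: int = 8
                  ) -> ModelSpec:
    return ModelSpec(
        architecture="densenet3d", input_shape=input_shape,
        conv_blocks=[(growth_rate, 3, "elu")] * n_blocks,
        spatial_dropout_rate=0.0, head="global_average_pooling")


@dataclass
class TrainingConfig:
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    balance: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ConfigError("only the adam optimizer is implemented")


class ProbabilityMatrix:
    """Row-stochastic (n, 20) matrix of per-residue class probabilities.

    Class order is the fixed alphabetical one-letter order ``AA_ORDER``;
    it is carried on the object and written into every persisted artefact.
    """

    def __init__(self, probs: np.ndarray, residues=None, skipped=None):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 20:
            raise ValueError("probability matrix must be (n, 20)")
        if np.any(probs < -1e-9):
            raise ValueError("negative probabilities")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-5):
            raise ValueError("rows must sum to 1 within 1e-5")
        self.probs = probs
        self.class_order = AA_ORDER
        self.residues = residues or []
        self.skipped = skipped or []

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, columns=list(self.class_order))


class NeuralModel:
    """A built network plus the spec and seed that produced it."""

    def __init__(self, net: nn.Sequential, spec: ModelSpec, seed: int):
        self.net = net
        self.spec = spec
        self.seed = seed
        self.head = spec.head

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def predict_proba(self, frames: np.ndarray, batch_size: int = 64
                      ) -> np.ndarray:
        frames = np.asarray(frames, dtype=np.float64)
        if frames.shape[1:] != self.spec.input_shape:
            raise ConfigError(
                f"frame shape {frames.shape[1:]} does not match model input "
                f"{self.spec.input_shape}")
        rows = []
        for start in range(0, frames.shape[0], batch_size):
            logits = self.net.forward(frames[start:start + batch_size])
            rows.append(nn.softmax(logits))
        return np.concatenate(rows, axis=0)


_ARCHITECTURES: dict[str, callable] = {}


def register_architecture(name: str):
    """Register a builder ``(spec, rng) -> Sequential`` under ``name``."""
    def wrap(builder):
        _ARCHITECTURES[name] = builder
        return builder
    return wrap


@register_architecture("timed")
def _build_timed(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    channels = spec.input_shape[-1]
    for filters, kernel, _act in spec.conv_blocks:
        layers.append(nn.Conv3D(channels, filters, kernel,
                                spec.conv_padding, rng=rng))
        layers.append(nn.ELU())
        layers.append(nn.Conv3D(filters, filters, kernel,
                                spec.conv_padding, rng=rng))
        layers.append(nn.ELU())
        layers.append(nn.SpatialDropout3D(
            spec.spatial_dropout_rate,
            rng=np.random.default_rng(rng.integers(2 ** 31))))
        channels = filters
    # network-in-network head: 1x1x1 conv to class channels, then GAP
    layers.append(nn.Conv3D(channels, spec.n_classes, 1, "valid", rng=rng))
    layers.append(nn.GlobalAveragePooling3D())
    return nn.Sequential(layers)


@register_architecture("prodconn_like")
def _build_prodconn(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    channels = spec.input_shape[-1]
    spatial = np.array(spec.input_shape[:3])
    for filters, kernel, _act in spec.conv_blocks:
        layers.append(nn.Conv3D(channels, filters, kernel, "valid", rng=rng))
        layers.append(nn.ELU())
        spatial = spatial - (kernel - 1)
        channels = filters
    layers.append(nn.Flatten())
    features = int(np.prod(spatial)) * channels
    for units in spec.dense_units:
        layers.append(nn.Dense(features, units, rng=rng))
        layers.append(nn.ELU())
        features = units
    layers.append(nn.Dense(features, spec.n_classes, rng=rng))
    return nn.Sequential(layers)


@register_architecture("densenet3d")
def _build_densenet(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    growth = spec.conv_blocks[0][0] if spec.conv_blocks else 8
    n_blocks = max(len(spec.conv_blocks), 1)
    layers: list[nn.Layer] = []
    block = nn.DenseBlock3D(spec.input_shape[-1], n_layers=2 * n_blocks,
                            growth_rate=growth, rng=rng)
    layers.append(block)
    layers.append(nn.Conv3D(block.out_channels, spec.n_classes, 1, "valid",
                            rng=rng))
    layers.append(nn.GlobalAveragePooling3D())
    return nn.Sequential(layers)


def build_model(spec: ModelSpec, seed: int = 0) -> NeuralModel:
    """Instantiate an untrained model for ``spec`` with seeded weights."""
    if spec.architecture not in _ARCHITECTURES:
        raise ConfigError(
            f"unknown architecture {spec.architecture!r}; "
            f"registered: {sorted(_ARCHITECTURES)}")
    rng = np.random.default_rng(seed)
    net = _ARCHITECTURES[spec.architecture](spec, rng)
    return NeuralModel(net, spec, seed)


def _macro_recall_from_labels(true_labels: np.ndarray,
                              pred_labels: np.ndarray) -> float:
    recalls = []
    for cls in np.unique(true_labels):
        mask = true_labels == cls
        recalls.append(float((pred_labels[mask] == cls).mean()))
    return float(np.mean(recalls)) if recalls else float("nan")


def train(model: NeuralModel, dataset: FrameDataset,
          config: TrainingConfig) -> pd.DataFrame:
    """Train in place; returns a per-epoch history table.

    With ``balance=True`` every epoch consumes
    :func:`voxdesign.dataset.balanced_epoch_indices` so each class present
    in the training split contributes equally; with ``balance=False`` the
    full (frequency-biased) training split is shuffled and consumed.
    History columns: epoch, loss, n_frames, class histogram of the frames
    consumed, and validation macro-recall when a validation split exists.
    """
    if "train" not in dataset.split_names:
        raise ValueError("dataset has no train split")
    train_idx = dataset.split("train")
    if train_idx.size == 0:
        raise ValueError("train split is empty")
    labels_all = dataset.labels
    optimizer = nn.Adam(model.net, learning_rate=config.learning_rate)
    shuffle_rng = np.random.default_rng([config.seed, 7919])
    has_val = "validation" in dataset.split_names \
        and dataset.split("validation").size > 0

    records = []
    for epoch in range(config.epochs):
        if config.balance:
            idx = balanced_epoch_indices(dataset, "train", epoch,
                                         config.seed).indices
        else:
            idx = shuffle_rng.permutation(train_idx)
        idx = idx[labels_all[idx] != UNKNOWN_LABEL]
        t0 = time.perf_counter()
        losses = []
        for start in range(0, idx.size, config.batch_size):
            batch = idx[start:start + config.batch_size]
            x = dataset.tensors(batch).astype(np.float64)
            y = labels_all[batch].astype(np.int64)
            logits = model.net.forward(x, training=True)
            loss, grad = nn.softmax_cross_entropy(logits, y)
            model.net.backward(grad)
            optimizer.step()
            losses.append(loss * batch.size)
        hist = np.bincount(labels_all[idx], minlength=20)[:20]
        row = {
            "epoch": epoch,
            "loss": float(np.sum(losses) / idx.size),
            "n_frames": int(idx.size),
            "class_histogram": json.dumps(hist.tolist()),
            "seconds": time.perf_counter() - t0,
        }
        if has_val:
            val_idx = dataset.split("validation")
            val_idx = val_idx[labels_all[val_idx] != UNKNOWN_LABEL]
            probs = model.predict_proba(dataset.tensors(val_idx))
            row["val_macro_recall"] = _macro_recall_from_labels(
                labels_all[val_idx], probs.argmax(axis=1))
        records.append(row)
    return pd.DataFrame.from_records(records)


def predict_structure(model: NeuralModel, structure: BackboneStructure,
                      config: VoxelConfig, constraints=None
                      ) -> ProbabilityMatrix:
    """Per-residue class probabilities for a backbone, one row per residue.

    Frames are predicted independently of each other.  ``constraints`` is a
    per-residue override vector for the property channel (design-time fixed
    sites) and requires ``config.property_channel != 'none'``.
    """
    if constraints is not None and config.property_channel == "none":
        raise ConfigError("constraints require a property channel")
    if config.tensor_shape() != model.spec.input_shape:
        raise ConfigError(
            f"voxel config produces {config.tensor_shape()}, model expects "
            f"{model.spec.input_shape}")
    frames, skipped = voxelise_structure(structure, config,
                                         constraints=constraints)
    tensors = np.stack([f.tensor for f in frames])
    probs = model.predict_proba(tensors)
    residues = [(f.chain_id, f.residue_index, f.amino_acid) for f in frames]
    return ProbabilityMatrix(probs, residues=residues, skipped=skipped)


def save_model(model: NeuralModel, path: str | Path,
               voxel_config: VoxelConfig | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar with spec and class order."""
    meta = {
        "spec": model.spec.to_dict(),
        "seed": model.seed,
        "class_order": AA_ORDER,
    }
    if voxel_config is not None:
        meta["voxel_config"] = voxel_config.to_dict()
    nn.save_net(model.net, path, meta=meta)


def load_model(path: str | Path) -> NeuralModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec.from_dict(meta["spec"])
    model = build_model(spec, seed=meta.get("seed", 0))
    model.net.load_state_arrays(nn.load_net_arrays(path))
    return model
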