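"""Frame dataset persistence (HDF5) and class-balanced epoch planning.

Amino-acid frequencies in natural proteins are far from uniform; training a
classifier on raw frame counts teaches it that prior.  The dataset layer
therefore supports *undersampling with per-epoch resampling*: each class is
capped at the rarest class's count, and at the start of every epoch the kept
subset of each over-represented class is redrawn from that class's full pool,
so the network sees many more unique frames over a run without frequency
bias in any single epoch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .constants import AA_ORDER, UNKNOWN_LABEL
from .voxelizer import Frame, VoxelConfig, voxelise_structure

log = logging.getLogger(__name__)

__all__ = [
    "FrameDataset",
    "EpochPlan",
    "build_dataset",
    "class_counts",
    "balanced_epoch_indices",
    "split_dataset",
]

_STR = h5py.string_dtype(encoding="utf-8")


@dataclass
class EpochPlan:
    """The frame indices one training epoch will consume."""

    epoch: int
    indices: np.ndarray
    seed: int


class FrameDataset:
    """An HDF5-backed collection of voxel frames with labels and splits.

    Layout: ``frames`` (N, V, V, V, C) float32, ``labels`` (N,) uint8 using
    255 for non-canonical residues, ``meta/structure_id|chain_id`` string
    arrays, ``meta/residue_index`` int32, ``splits/<name>`` int64 index
    arrays, and the :class:`VoxelConfig` as a JSON attribute.
    """

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, mode)

    # -- construction -----------------------------------------------------
    @classmethod
    def create(cls, path: str | Path, frames: list[Frame],
               config: VoxelConfig) -> "FrameDataset":
        if not frames:
            raise ValueError("no frames to store")
        shape = frames[0].tensor.shape
        if any(f.tensor.shape != shape for f in frames):
            raise ValueError("inconsistent frame tensor shapes")
        with h5py.File(path, "w") as h5:
            h5.create_dataset(
                "frames",
                data=np.stack([f.tensor for f in frames]).astype(np.float32))
            h5.create_dataset(
                "labels",
                data=np.array([f.label for f in frames], dtype=np.uint8))
            meta = h5.create_group("meta")
            meta.create_dataset(
                "structure_id",
                data=np.array([f.structure_id for f in frames], dtype=object),
                dtype=_STR)
            meta.create_dataset(
                "chain_id",
                data=np.array([f.chain_id for f in frames], dtype=object),
                dtype=_STR)
            meta.create_dataset(
                "residue_index",
                data=np.array([f.residue_index for f in frames], dtype=np.int32))
            h5.create_group("splits")
            h5.attrs["voxel_config"] = json.dumps(config.to_dict())
            h5.attrs["class_order"] = AA_ORDER
        return cls(path, mode="r+")

    # -- accessors --------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self._h5["labels"].shape[0]

    @property
    def tensor_shape(self) -> tuple[int, ...]:
        return tuple(self._h5["frames"].shape[1:])

    @property
    def labels(self) -> np.ndarray:
        return self._h5["labels"][...]

    @property
    def config(self) -> VoxelConfig:
        return VoxelConfig.from_dict(json.loads(self._h5.attrs["voxel_config"]))

    def tensors(self, indices=None) -> np.ndarray:
        if indices is None:
            return self._h5["frames"][...]
        indices = np.asarray(indices)
        order = np.argsort(indices)
        sorted_t = self._h5["frames"][np.sort(indices), ...]
        out = np.empty_like(sorted_t)
        out[order] = sorted_t
        return out

    def structure_ids(self) -> np.ndarray:
        return self._h5["meta/structure_id"].asstr()[...]

    def meta(self, index: int) -> dict:
        return {
            "structure_id": self._h5["meta/structure_id"].asstr()[index],
            "chain_id": self._h5["meta/chain_id"].asstr()[index],
            "residue_index": int(self._h5["meta/residue_index"][index]),
        }

    # -- splits -----------------------------------------------------------
    @property
    def split_names(self) -> list[str]:
        return list(self._h5["splits"].keys())

    def set_split(self, name: str, indices) -> None:
        grp = self._h5["splits"]
        if name in grp:
            del grp[name]
        grp.create_dataset(name, data=np.asarray(indices, dtype=np.int64))
        self._h5.flush()

    def split(self, name: str) -> np.ndarray:
        if name not in self._h5["splits"]:
            raise KeyError(f"no split {name!r} (have {self.split_names})")
        return self._h5["splits"][name][...]

    # -- lifecycle --------------------------------------------------------
    def close(self) -> None:
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def __len__(self) -> int:
        return self.n_frames


def build_dataset(structures, config: VoxelConfig, path: str | Path
                  ) -> FrameDataset:
    """Voxelise every residue of every structure and persist the frames.

    Record order is deterministic: structures in input order, residues in
    chain/sequence order.
    """
    frames: list[Frame] = []
    n_skipped = 0
    for structure in structures:
        fs, skipped = voxelise_structure(structure, config)
        frames.extend(fs)
        n_skipped += len(skipped)
    if n_skipped:
        log.warning("skipped %d residues during voxelisation", n_skipped)
    return FrameDataset.create(path, frames, config)


def class_counts(dataset: FrameDataset, split: str | None = None) -> np.ndarray:
    """Per-class frame counts (length 20, AA_ORDER) for a split."""
    labels = dataset.labels
    if split is not None:
        labels = labels[dataset.split(split)]
    labels = labels[labels != UNKNOWN_LABEL]
    return np.bincount(labels, minlength=20)[:20]


def balanced_epoch_indices(dataset: FrameDataset, split: str, epoch: int,
                           seed: int) -> EpochPlan:
    """Undersampled, shuffled frame indices for one epoch.

    The cap is the smallest nonzero class count in the split.  Classes above
    the cap contribute a fresh uniform subset (without replacement) drawn
    from their *full* pool each epoch — the stream is keyed by
    ``(seed, epoch)``, so plans are reproducible yet differ across epochs.
    Classes at or below the cap are included in full.
    """
    split_idx = dataset.split(split)
    if split_idx.size == 0:
        raise ValueError(f"split {split!r} is empty")
    labels = dataset.labels[split_idx]
    counts = np.bincount(labels[labels != UNKNOWN_LABEL], minlength=20)[:20]
    present = np.nonzero(counts)[0]
    if present.size < 20:
        log.info("split %r has only %d/20 classes present; cap uses the "
                 "smallest nonzero count", split, present.size)
    cap = int(counts[present].min())
    rng = np.random.default_rng([seed, epoch])
    chosen = []
    for cls in present:
        pool = split_idx[labels == cls]
        if pool.size > cap:
            chosen.append(rng.choice(pool, size=cap, replace=False))
        else:
            chosen.append(pool)
    indices = np.concatenate(chosen)
    rng.shuffle(indices)
    return EpochPlan(epoch=epoch, indices=indices, seed=seed)


def split_dataset(dataset: FrameDataset, fractions, seed: int) -> dict:
    """Assign train/validation/test splits at *structure* granularity.

    ``fractions`` is a sequence of 1-3 positive floats summing to at most 1,
    interpreted as (train, validation, test).  Frames of one structure never
    straddle splits, avoiding leakage between overlapping frames.
    """
    fractions = list(fractions)
    if not fractions or any(f <= 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
        raise ValueError("fractions must be positive and sum to at most 1")
    names = ["train", "validation", "test"][: len(fractions)]

    sids = dataset.structure_ids()
    unique = sorted(set(sids))
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique))
    n = len(order)
    bounds = np.floor(np.cumsum(fractions) * n + 1e-9).astype(int)
    splits: dict[str, np.ndarray] = {}
    start = 0
    for name, stop in zip(names, bounds):
        members = set(order[start:stop])
        splits[name] = np.nonzero(np.isin(sids, list(members)))[0]
        start = stop
    for name, idx in splits.items():
        dataset.set_split(name, idx)
    return splits
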