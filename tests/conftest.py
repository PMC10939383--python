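"""Shared fixtures: ideal backbones, a small voxel config, and one trained
tiny model reused by every test that needs a classifier."""

from __future__ import annotations

import numpy as np
import pytest

import voxdesign as vd


@pytest.fixture(scope="session")
def tiny_config() -> vd.VoxelConfig:
    """Desk-scale frames: 12 A cube at 9 voxels per edge."""
    return vd.VoxelConfig(frame_edge_length=12.0, voxels_per_side=9)


@pytest.fixture(scope="session")
def helix12() -> vd.BackboneStructure:
    return vd.make_helix(12)


@pytest.fixture(scope="session")
def strand12() -> vd.BackboneStructure:
    return vd.make_strand(12)


@pytest.fixture(scope="session")
def synthetic_ds(tmp_path_factory, tiny_config):
    """600-frame geometry-labelled dataset with skewed class counts."""
    path = tmp_path_factory.mktemp("data") / "synthetic.h5"
    ds = vd.synthetic_labelled_dataset(20, 30, seed=11, config=tiny_config,
                                       path=path)
    yield ds
    ds.close()


@pytest.fixture(scope="session")
def tiny_spec(tiny_config) -> vd.ModelSpec:
    return vd.timed_spec(tiny_config.tensor_shape(),
                         conv_blocks=[(8, 3, "elu"), (16, 3, "elu")],
                         conv_padding="valid")


@pytest.fixture(scope="session")
def trained_model(synthetic_ds, tiny_spec):
    """Tiny TIMED-style model trained 15 balanced epochs on the synthetic
    task; shared across tests to keep the suite fast."""
    model = vd.build_model(tiny_spec, seed=3)
    history = vd.train(model, synthetic_ds,
                       vd.TrainingConfig(epochs=15, batch_size=32, seed=3,
                                         balance=True))
    return model, history


def macro_recall_of(labels: np.ndarray, predictions: np.ndarray) -> float:
    recalls = [float((predictions[labels == c] == c).mean())
               for c in np.unique(labels)]
    return float(np.mean(recalls))
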