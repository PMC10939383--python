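"""Residue classifier construction, training behaviour, and prediction."""

import numpy as np
import pytest

import voxdesign as vd
from voxdesign.errors import ConfigError

from conftest import macro_recall_of


class TestBuildModel:
    def test_timed_forward_is_row_stochastic(self, tiny_spec, tiny_config):
        model = vd.build_model(tiny_spec, seed=0)
        x = np.random.default_rng(0).random((2, *tiny_config.tensor_shape()))
        p = model.predict_proba(x)
        assert p.shape == (2, 20)
        assert np.all(p >= 0)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-9

    def test_prodconn_has_flatten_dense_head(self, tiny_config):
        spec = vd.prodconn_spec(tiny_config.tensor_shape(),
                                conv_blocks=[(4, 3, "elu")],
                                dense_units=[16])
        model = vd.build_model(spec, seed=0)
        assert model.head == "flatten_dense"
        assert any(type(l).__name__ == "Flatten" for l in model.net.layers)
        assert not any(type(l).__name__ == "GlobalAveragePooling3D"
                       for l in model.net.layers)

    def test_timed_has_no_dense_layer(self, tiny_spec):
        model = vd.build_model(tiny_spec, seed=0)
        assert model.head == "global_average_pooling"
        assert not any(type(l).__name__ == "Dense" for l in model.net.layers)

    def test_densenet_builds_and_predicts(self, tiny_config):
        spec = vd.densenet_spec(tiny_config.tensor_shape(), n_blocks=1,
                                growth_rate=4)
        model = vd.build_model(spec, seed=0)
        x = np.random.default_rng(1).random((2, *tiny_config.tensor_shape()))
        p = model.predict_proba(x)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-9

    def test_same_spec_and_seed_is_deterministic(self, tiny_spec,
                                                 tiny_config):
        x = np.random.default_rng(2).random((3, *tiny_config.tensor_shape()))
        p1 = vd.build_model(tiny_spec, seed=7).predict_proba(x)
        p2 = vd.build_model(tiny_spec, seed=7).predict_proba(x)
        assert np.array_equal(p1, p2)

    def test_spec_invariants_enforced(self, tiny_config):
        shape = tiny_config.tensor_shape()
        with pytest.raises(ConfigError):
            vd.ModelSpec("timed", shape, head="flatten_dense")
        with pytest.raises(ConfigError):
            vd.ModelSpec("timed", shape, spatial_dropout_rate=0.0)
        with pytest.raises(ConfigError):
            vd.ModelSpec("prodconn_like", shape,
                         head="global_average_pooling")
        with pytest.raises(ConfigError):
            vd.build_model(vd.ModelSpec("no_such_net", shape,
                                        head="flatten_dense"))

    def test_architecture_registry_is_extensible(self, tiny_config):
        @vd.register_architecture("linear_probe")
        def _build(spec, rng):
            from voxdesign import nn
            return nn.Sequential([
                nn.Flatten(),
                nn.Dense(int(np.prod(spec.input_shape)), spec.n_classes,
                         rng=rng)])
        spec = vd.ModelSpec("linear_probe", tiny_config.tensor_shape(),
                            head="flatten_dense")
        model = vd.build_model(spec, seed=0)
        assert model.n_parameters > 0


class TestTraining:
    def test_learns_geometry_labels(self, synthetic_ds, trained_model):
        """The label rule is a deterministic function of frame geometry, so
        a consistent classifier must recover it on held-out frames."""
        model, history = trained_model
        labels = synthetic_ds.labels
        test_idx = synthetic_ds.split("test")
        probs = model.predict_proba(synthetic_ds.tensors(test_idx))
        assert macro_recall_of(labels[test_idx], probs.argmax(1)) >= 0.9

    def test_balanced_epochs_consume_uniform_histograms(self, trained_model):
        import json
        _, history = trained_model
        for hist_json in history["class_histogram"]:
            hist = np.array(json.loads(hist_json))
            present = hist[hist > 0]
            assert present.size == 3
            assert present.min() == present.max()

    def test_unbalanced_training_prefers_majority_class(self, synthetic_ds,
                                                        tiny_spec):
        """Paired under-trained runs at a fixed seed: without balancing the
        majority class is predicted more often (class-balanced reference)."""
        labels = synthetic_ds.labels
        test_idx = synthetic_ds.split("test")
        counts = np.bincount(labels[test_idx], minlength=20)
        present = np.nonzero(counts)[0]
        per = counts[present].min()
        sel = np.concatenate([test_idx[labels[test_idx] == c][:per]
                              for c in present])
        majority = int(np.argmax(np.bincount(labels[synthetic_ds
                                                    .split("train")],
                                             minlength=20)))
        freqs = {}
        for balance in (True, False):
            model = vd.build_model(tiny_spec, seed=11)
            vd.train(model, synthetic_ds,
                     vd.TrainingConfig(epochs=1, batch_size=32, seed=11,
                                       balance=balance))
            pred = model.predict_proba(synthetic_ds.tensors(sel)).argmax(1)
            freqs[balance] = float((pred == majority).mean())
        assert freqs[False] > freqs[True]

    def test_history_schema_and_reproducibility(self, synthetic_ds,
                                                tiny_spec):
        def run():
            model = vd.build_model(tiny_spec, seed=2)
            return vd.train(model, synthetic_ds,
                            vd.TrainingConfig(epochs=2, batch_size=32,
                                              seed=2, balance=True))
        h1, h2 = run(), run()
        assert list(h1["epoch"]) == [0, 1]
        assert np.allclose(h1["loss"], h2["loss"])
        assert "val_macro_recall" in h1.columns

    def test_missing_train_split_rejected(self, tmp_path, tiny_config,
                                          tiny_spec):
        ds = vd.build_dataset([vd.make_helix(8)], tiny_config,
                              tmp_path / "nosplit.h5")
        model = vd.build_model(tiny_spec, seed=0)
        with pytest.raises(ValueError):
            vd.train(model, ds, vd.TrainingConfig(epochs=1))
        ds.close()


class TestPredictStructure:
    def test_output_contract(self, trained_model, tiny_config):
        model, _ = trained_model
        helix = vd.make_helix(30)
        matrix = vd.predict_structure(model, helix, tiny_config)
        assert matrix.probs.shape == (30, 20)
        assert np.abs(matrix.probs.sum(axis=1) - 1).max() < 1e-5

    def test_rigid_motion_invariance_end_to_end(self, trained_model,
                                                tiny_config):
        model, _ = trained_model
        helix = vd.make_helix(10)
        motion = vd.random_rigid_transform(np.random.default_rng(23))
        moved = helix.transformed(motion)
        vd.add_virtual_cbetas(moved)
        p1 = vd.predict_structure(model, helix, tiny_config).probs
        p2 = vd.predict_structure(model, moved, tiny_config).probs
        assert np.abs(p1 - p2).max() < 1e-4

    def test_config_shape_mismatch_rejected(self, trained_model):
        model, _ = trained_model
        with pytest.raises(ConfigError):
            vd.predict_structure(model, vd.make_helix(6), vd.VoxelConfig())

    def test_constraints_require_property_channel(self, trained_model,
                                                  tiny_config):
        model, _ = trained_model
        with pytest.raises(ConfigError):
            vd.predict_structure(model, vd.make_helix(6), tiny_config,
                                 constraints=[0] * 6)


class TestPersistence:
    def test_save_load_preserves_predictions(self, trained_model,
                                             tiny_config, tmp_path):
        model, _ = trained_model
        helix = vd.make_helix(8)
        before = vd.predict_structure(model, helix, tiny_config).probs
        vd.save_model(model, tmp_path / "m.npz", voxel_config=tiny_config)
        loaded = vd.load_model(tmp_path / "m.npz")
        after = vd.predict_structure(loaded, helix, tiny_config).probs
        assert np.array_equal(before, after)
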