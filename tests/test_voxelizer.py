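"""Frame tensors: geometry, invariance, density modes, property channels."""

import numpy as np
import pytest

import voxdesign as vd
from voxdesign.constants import AA_ORDER, ZIMMERMAN_POLARITY
from voxdesign.errors import ConfigError, ConstraintError


class TestVoxelConfig:
    def test_default_matches_published_frame_geometry(self):
        cfg = vd.VoxelConfig()
        assert cfg.frame_edge_length == 12.0
        assert cfg.voxels_per_side == 21
        assert cfg.tensor_shape() == (21, 21, 21, 5)

    @pytest.mark.parametrize("kwargs", [
        {"voxels_per_side": 20},
        {"frame_edge_length": -1.0},
        {"atom_encoding": "XYZ"},
        {"density_mode": "fuzzy"},
        {"property_channel": "mass"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            vd.VoxelConfig(**kwargs)

    def test_property_channel_adds_one_channel(self):
        assert vd.VoxelConfig(property_channel="charge").n_channels == 6
        assert vd.VoxelConfig(atom_encoding="CNO").n_channels == 3


class TestVoxeliseFrame:
    def test_default_shape_and_central_ca(self, helix12):
        frame = vd.voxelise_frame(helix12, "A", 5, vd.VoxelConfig())
        assert frame.tensor.shape == (21, 21, 21, 5)
        ca_channel = frame.tensor[..., 4]
        assert np.unravel_index(ca_channel.argmax(), ca_channel.shape) \
            == (10, 10, 10)

    def test_rigid_motion_invariance(self, helix12, tiny_config):
        rng = np.random.default_rng(17)
        motion = vd.random_rigid_transform(rng)
        moved = helix12.transformed(motion)
        vd.add_virtual_cbetas(moved)
        for i in (0, 5, 11):
            f1 = vd.voxelise_frame(helix12, "A", i, tiny_config)
            f2 = vd.voxelise_frame(moved, "A", i, tiny_config)
            assert np.abs(f1.tensor - f2.tensor).max() < 1e-6

    def test_gaussian_peak_at_atom_voxel(self, helix12):
        cfg = vd.VoxelConfig()
        frame = vd.voxelise_frame(helix12, "A", 5, cfg)
        ca = frame.tensor[..., 4]
        centre = ca[10, 10, 10]
        neighbours = [ca[10 + d, 10, 10] for d in (-1, 1)] \
            + [ca[10, 10 + d, 10] for d in (-1, 1)] \
            + [ca[10, 10, 10 + d] for d in (-1, 1)]
        assert all(centre >= v for v in neighbours)

    def test_occupancy_mode_is_binary(self, helix12, tiny_config):
        cfg = vd.VoxelConfig(frame_edge_length=12.0, voxels_per_side=9,
                             density_mode="occupancy")
        frame = vd.voxelise_frame(helix12, "A", 5, cfg)
        assert set(np.unique(frame.tensor)) <= {0.0, 1.0}
        # occupied voxels cannot exceed the number of rendered atoms
        n_atoms = 5 * helix12.n_residues
        assert frame.tensor.sum() <= n_atoms

    def test_shrinking_cube_cannot_gain_atoms(self, helix12):
        def occupied(edge):
            cfg = vd.VoxelConfig(frame_edge_length=edge, voxels_per_side=9,
                                 density_mode="occupancy")
            return vd.voxelise_frame(helix12, "A", 5, cfg).tensor.sum()
        assert occupied(8.0) <= occupied(12.0) <= occupied(16.0)

    def test_one_frame_per_residue_and_label_consistency(self, helix12,
                                                         tiny_config):
        frames, skipped = vd.voxelise_structure(helix12, tiny_config)
        assert len(frames) == helix12.n_residues and not skipped
        letters = "".join(AA_ORDER[f.label] for f in frames)
        assert letters == helix12.sequence()


class TestPropertyAssignments:
    def test_zimmerman_polarity_partition(self):
        polar = {aa for aa in AA_ORDER if vd.assign_polarity(aa) == 1}
        nonpolar = {aa for aa in AA_ORDER if vd.assign_polarity(aa) == -1}
        assert polar == {"R", "K", "H", "D", "E"}
        assert polar | nonpolar == set(AA_ORDER)
        assert not polar & nonpolar

    def test_polarity_follows_packaged_scale(self):
        for aa in AA_ORDER:
            expected = -1 if ZIMMERMAN_POLARITY[aa] < 20 else 1
            assert vd.assign_polarity(aa) == expected

    @pytest.mark.parametrize("aa,expected", [
        ("D", -1), ("E", -1), ("K", 1), ("R", 1), ("H", 1),
        ("G", 0), ("A", 0), ("W", 0),
    ])
    def test_charge_classes(self, aa, expected):
        assert vd.assign_charge(aa) == expected

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            vd.assign_polarity("B")
        with pytest.raises(KeyError):
            vd.assign_charge("Z")


class TestPropertyChannel:
    def test_charge_channel_all_zero_for_glycine(self):
        coil = vd.make_coil(8)  # all-glycine sequence
        cfg = vd.VoxelConfig(frame_edge_length=12.0, voxels_per_side=9,
                             property_channel="charge")
        frame = vd.voxelise_frame(coil, "A", 4, cfg)
        assert np.all(frame.tensor[..., 5] == 0)
        assert frame.property_value == 0

    def test_polarity_channel_support(self, helix12):
        cfg = vd.VoxelConfig(frame_edge_length=12.0, voxels_per_side=9,
                             property_channel="polarity")
        frame = vd.voxelise_frame(helix12, "A", 5, cfg)
        values = np.unique(frame.tensor[..., 5])
        assert set(values) <= {-1.0, 0.0, 1.0}
        nonzero = np.count_nonzero(frame.tensor[..., 5])
        assert 1 <= nonzero <= helix12.n_residues

    def test_constraint_override_changes_one_voxel(self, helix12):
        cfg = vd.VoxelConfig(frame_edge_length=12.0, voxels_per_side=9,
                             property_channel="polarity")
        base = vd.voxelise_frame(helix12, "A", 5, cfg)
        constraints = [None] * helix12.n_residues
        constraints[5] = +1  # alanine is non-polar (-1) by sequence
        forced = vd.voxelise_frame(helix12, "A", 5, cfg,
                                   constraints=constraints)
        diff = base.tensor[..., 5] != forced.tensor[..., 5]
        assert diff.sum() == 1
        assert np.abs(base.tensor[..., :5] - forced.tensor[..., :5]).max() == 0

    def test_constraint_length_mismatch_rejected(self, helix12):
        cfg = vd.VoxelConfig(property_channel="charge")
        with pytest.raises(ConstraintError):
            vd.voxelise_frame(helix12, "A", 0, cfg, constraints=[0, 1])
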