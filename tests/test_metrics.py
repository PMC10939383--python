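"""Sequence and shape evaluation metrics."""

import numpy as np
import pytest

import voxdesign as vd
from voxdesign.constants import AA_ORDER


class TestConfusionAndRecall:
    def test_constant_predictor_capped_at_five_percent(self):
        reference = AA_ORDER  # all 20 classes, one each
        prediction = "A" * 20
        report = vd.confusion_and_recall(reference, prediction)
        assert report.macro_recall == pytest.approx(0.05)

    def test_perfect_prediction(self):
        report = vd.confusion_and_recall("ACDEFG", "ACDEFG")
        assert report.macro_recall == 1.0
        assert report.accuracy == 1.0
        assert np.trace(report.confusion) == 6

    def test_hand_enumerated_three_class_example(self):
        report = vd.confusion_and_recall("AAVVG", "AVVVG")
        per = report.per_class
        assert per["A"]["recall"] == pytest.approx(0.5)
        assert per["V"]["recall"] == pytest.approx(1.0)
        assert per["G"]["recall"] == pytest.approx(1.0)
        assert report.macro_recall == pytest.approx(5 / 6)
        assert report.accuracy == pytest.approx(4 / 5)

    def test_strict_mode_divides_by_twenty(self):
        report = vd.confusion_and_recall("AAVVG", "AVVVG", strict=True)
        assert report.macro_recall == pytest.approx((0.5 + 1 + 1) / 20)

    def test_unknown_positions_dropped_and_counted(self):
        report = vd.confusion_and_recall("AXG", "AAG")
        assert report.metadata["n_dropped"] == 1
        assert report.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vd.confusion_and_recall("AAA", "AA")

    def test_random_predictor_macro_recall_near_five_percent(self):
        rng = np.random.default_rng(0)
        n = 100_000
        ref = "".join(rng.choice(list(AA_ORDER), n))
        pred = "".join(rng.choice(list(AA_ORDER), n))
        report = vd.confusion_and_recall(ref, pred)
        assert abs(report.macro_recall - 0.05) < 0.01


class TestPredictionBias:
    def test_identical_sequences_have_zero_bias(self):
        bias = vd.prediction_bias(["ACDEF"], ["ACDEF"])
        assert all(v == 0 for v in bias.values())

    def test_hand_enumerated_example(self):
        bias = vd.prediction_bias(["AG"], ["AA"])
        assert bias["A"] == pytest.approx(50.0)
        assert bias["G"] == pytest.approx(-50.0)
        assert all(bias[a] == 0 for a in AA_ORDER if a not in "AG")

    def test_biases_sum_to_zero(self):
        rng = np.random.default_rng(1)
        refs = ["".join(rng.choice(list(AA_ORDER), 50)) for _ in range(5)]
        preds = ["".join(rng.choice(list(AA_ORDER), 50)) for _ in range(5)]
        assert abs(sum(vd.prediction_bias(refs, preds).values())) < 1e-9


class TestChargeAndIsoelectricPoint:
    def test_charge_sign_sanity(self):
        assert vd.sequence_charge("KKKK", 7.0) > 0
        assert vd.sequence_charge("DDDD", 7.0) < 0

    def test_charge_strictly_decreasing_in_ph(self):
        for seq in ("ACDEFGHIKLMNPQRSTVWY", "KKDD", "GGGG"):
            charges = [vd.sequence_charge(seq, ph)
                       for ph in np.linspace(0, 14, 30)]
            assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_pi_zeroes_the_charge_and_matches_grid_scan(self):
        for seq in ("ACDKRS", "DDEEKK", "GAVLIM"):
            pi = vd.isoelectric_point(seq)
            assert abs(vd.sequence_charge(seq, pi)) < 1e-4
            grid = np.arange(0.0, 14.0, 1e-4)
            charges = np.abs([vd.sequence_charge(seq, ph) for ph in
                              np.arange(round(pi) - 2, round(pi) + 2, 1e-3)])
            grid_pi = np.arange(round(pi) - 2, round(pi) + 2,
                                1e-3)[np.argmin(charges)]
            assert abs(pi - grid_pi) < 1e-2

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            vd.sequence_charge("")


class TestMae:
    def test_identical_vectors(self):
        assert vd.mae([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert vd.mae([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert vd.mae(a, b) == pytest.approx(vd.mae(b, a))
        assert vd.mae(a, b) >= 0
        with pytest.raises(ValueError):
            vd.mae([1.0], [1.0, 2.0])


class TestEntropy:
    def test_uniform_rows_attain_log2_twenty(self):
        mean, per_row = vd.mean_entropy(np.full((7, 20), 1 / 20))
        assert round(mean, 2) == 4.32
        assert np.abs(per_row - np.log2(20)).max() < 1e-12

    def test_one_hot_rows_have_zero_entropy(self):
        assert vd.mean_entropy(np.eye(20))[0] == 0.0

    def test_two_point_row_is_one_bit(self):
        row = np.zeros((1, 20))
        row[0, :2] = 0.5
        assert vd.mean_entropy(row)[0] == pytest.approx(1.0)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        m = rng.dirichlet(np.ones(20), size=9)
        assert vd.mean_entropy(m)[0] == pytest.approx(
            vd.mean_entropy(m[::-1])[0])


class TestRmsd100:
    def test_length_one_hundred_is_identity(self):
        assert vd.rmsd100(1.7, 100) == pytest.approx(1.7)

    def test_closed_form_at_length_400(self):
        assert vd.rmsd100(2.0, 400) == pytest.approx(2.0 / (1 + np.log(2)))

    def test_zero_rmsd_maps_to_zero(self):
        for n in (1, 50, 100, 1000):
            assert vd.rmsd100(0.0, n) == 0.0
        with pytest.raises(ValueError):
            vd.rmsd100(1.0, 0)


class TestStructureRmsd:
    def test_rigid_copy_scores_zero(self, helix12):
        moved = helix12.transformed(
            vd.random_rigid_transform(np.random.default_rng(4)))
        r, r100 = vd.structure_rmsd(helix12, moved)
        assert r < 1e-6 and r100 < 1e-6

    def test_uniform_displacement_after_superposition(self, helix12):
        """Displacing every CA by the same vector is absorbed by the
        superposition translation, so the RMSD stays zero; the value is
        cross-checked against the Kabsch oracle on raw coordinates."""
        shift = np.array([0.6, -0.8, 0.0])
        moved = helix12.transformed(vd.RigidTransform(np.eye(3), shift))
        r, r100 = vd.structure_rmsd(helix12, moved)
        _, oracle = vd.kabsch_superpose(helix12.ca_coords(),
                                        moved.ca_coords())
        assert r == pytest.approx(oracle)
        assert r < 1e-9
        assert r100 == pytest.approx(vd.rmsd100(r, helix12.n_residues))

    def test_jittered_copy_matches_kabsch_oracle(self, helix12):
        rng = np.random.default_rng(5)
        jittered = helix12.transformed(vd.RigidTransform(np.eye(3),
                                                         np.zeros(3)))
        for res in jittered.residues():
            res.ca_coord = res.ca_coord + rng.normal(0, 0.5, 3)
        r, r100 = vd.structure_rmsd(helix12, jittered)
        _, oracle = vd.kabsch_superpose(helix12.ca_coords(),
                                        jittered.ca_coords())
        assert r == pytest.approx(oracle)
        assert r > 0
        assert r100 == pytest.approx(vd.rmsd100(r, 12))


class TestPackingDensity:
    def test_single_residue_counts_its_own_atoms(self):
        helix = vd.make_helix(4)
        single = vd.BackboneStructure(
            "one", [vd.Chain("A", [helix.chains[0].residues[0]])])
        counts, mean = vd.packing_density(single)
        assert counts.tolist() == [4]  # its own N, CA, C, O
        assert mean == 4.0

    def test_monotone_in_radius(self, helix12):
        c5, _ = vd.packing_density(helix12, radius=5.0)
        c7, _ = vd.packing_density(helix12, radius=7.0)
        assert np.all(c7 >= c5)

    def test_helix_packs_denser_than_strand(self):
        _, helix_mean = vd.packing_density(vd.make_helix(20))
        _, strand_mean = vd.packing_density(vd.make_strand(20))
        assert helix_mean > strand_mean


class TestEvaluateSequences:
    def test_full_report_on_identical_pairs(self):
        seqs = ["ACDKRS", "GAVLIM"]
        report = vd.evaluate_sequences(seqs, seqs)
        assert report.macro_recall == 1.0
        assert report.charge_mae == 0.0
        assert report.pi_mae == 0.0
        assert all(v == 0 for v in report.bias.values())
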