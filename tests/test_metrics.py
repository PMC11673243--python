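"""Six-metric evaluation suite: examples, identities, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselfield.metrics import (
    MetricsReport,
    chamfer_l2,
    cl_dice,
    dice,
    evaluate,
    iou,
    re_error,
    re_mse,
    summarize_reports,
)


def random_pair(seed, shape=(6, 6, 6), p=0.3):
    rng = np.random.default_rng(seed)
    return rng.random(shape) < p, rng.random(shape) < p


class TestDiceIou:
    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert iou(a, a) == 1.0
        assert iou(a, ~a) == 0.0

    def test_counted_example(self):
        p = np.zeros(10, bool)
        g = np.zeros(10, bool)
        p[:3] = True  # |P| = 3
        g[1:4] = True  # |G| = 3, overlap {1,2} = 2
        assert dice(p, g) == pytest.approx(2 * 2 / 6)
        # |P&G| = 2, |P|G| = 4
        assert iou(p, g) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0
        assert iou(z, z) == 1.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None)
    def test_dice_iou_identity(self, seed):
        p, g = random_pair(seed)
        d, j = dice(p, g), iou(p, g)
        assert d == pytest.approx(2 * j / (1 + j))

    def test_symmetry(self):
        p, g = random_pair(1)
        assert dice(p, g) == dice(g, p)
        assert iou(p, g) == iou(g, p)

    def test_adding_correct_voxel_never_decreases_dice(self):
        p, g = random_pair(5)
        missing = np.logical_and(g, ~p)
        idx = np.argwhere(missing)[0]
        p2 = p.copy()
        p2[tuple(idx)] = True
        assert dice(p2, g) >= dice(p, g)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestClDice:
    def test_identical_volumes_score_one(self):
        vol = np.zeros((10, 10, 10), bool)
        vol[2:8, 4:6, 4:6] = True
        assert cl_dice(vol, vol) == 1.0

    def test_mutual_skeleton_containment_scores_one(self):
        g = np.zeros((12, 12, 12), bool)
        g[2:10, 5:8, 5:8] = True
        p = np.zeros_like(g)
        p[2:10, 4:9, 4:9] = True  # dilated tube: contains gt skeleton
        # both skeletons run along the common core
        if cl_dice(p, g) != pytest.approx(1.0):
            # containment both ways is required for exactly 1
            from skimage.morphology import skeletonize

            assert np.all(g[skeletonize(p)])

    def test_tube_with_missing_middle_matches_brute_force(self):
        """A 1-voxel tube vs the same tube missing its middle third."""
        from skimage.morphology import skeletonize

        g = np.zeros((15, 7, 7), bool)
        g[1:14, 3, 3] = True  # 13-voxel straight tube
        p = g.copy()
        p[5:10, 3, 3] = False  # remove the middle
        skel_p = skeletonize(p)
        skel_g = skeletonize(g)
        tprec = np.logical_and(skel_p, g).sum() / skel_p.sum()
        tsens = np.logical_and(skel_g, p).sum() / skel_g.sum()
        expected = 2 * tprec * tsens / (tprec + tsens)
        assert cl_dice(p, g) == pytest.approx(expected)
        assert cl_dice(p, g) < 1.0

    def test_one_empty_volume_scores_zero(self):
        g = np.zeros((5, 5, 5), bool)
        p = g.copy()
        p[2, 2, 2] = True
        assert cl_dice(p, g) == 0.0
        assert cl_dice(g, p) == 0.0
        assert cl_dice(g, g) == 1.0


class TestChamfer:
    def test_identical_sets_zero(self):
        p, _ = random_pair(3)
        assert chamfer_l2(p, p, (1, 1, 1)) == 0.0

    def test_two_points_three_mm_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True  # 3 voxels at 1 mm spacing
        assert chamfer_l2(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        assert chamfer_l2(a, b, (0.5, 1.0, 1.0)) == pytest.approx(1.5)

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            p = rng.random((7, 7, 7)) < 0.25
            g = rng.random((7, 7, 7)) < 0.25
            if not p.any() or not g.any():
                continue
            spacing = (0.7, 1.1, 0.9)
            pts_p = np.argwhere(p) * np.asarray(spacing)
            pts_g = np.argwhere(g) * np.asarray(spacing)
            d_pg = np.array(
                [min(np.linalg.norm(x - y) for y in pts_g) for x in pts_p]
            )
            d_gp = np.array(
                [min(np.linalg.norm(y - x) for x in pts_p) for y in pts_g]
            )
            expected = 0.5 * (d_pg.mean() + d_gp.mean())
            assert chamfer_l2(p, g, spacing) == pytest.approx(expected, rel=1e-12)

    def test_symmetry(self):
        p, g = random_pair(9)
        assert chamfer_l2(p, g, (1, 1, 1)) == pytest.approx(
            chamfer_l2(g, p, (1, 1, 1))
        )

    def test_one_empty_is_undefined(self):
        z = np.zeros((4, 4, 4), bool)
        o = z.copy()
        o[1, 1, 1] = True
        assert np.isnan(chamfer_l2(o, z, (1, 1, 1)))
        assert chamfer_l2(z, z, (1, 1, 1)) == 0.0


class TestErrorRates:
    def test_perfect_reconstruction(self):
        _, g = random_pair(2)
        g = g | np.eye(6, dtype=bool)[:, :, None].repeat(6, 2)  # ensure nonempty
        assert re_error(g, g) == 0.0
        assert re_mse(g, g) == 0.0

    def test_counted_false_positive_negative_example(self):
        g = np.zeros(200, bool)
        g[:100] = True
        p = g.copy()
        p[:7] = False  # 7 FN
        p[100:107] = True  # 7 FP
        assert re_error(p, g) == pytest.approx(0.14)
        assert re_mse(p, g) == pytest.approx(14 / 200)

    def test_empty_prediction_scores_one(self):
        g = np.zeros((4, 4, 4), bool)
        g[1:3, 1:3, 1:3] = True
        assert re_error(np.zeros_like(g), g) == pytest.approx(1.0)

    def test_empty_ground_truth_undefined(self):
        with pytest.raises(ValueError):
            re_error(np.ones((2, 2, 2)), np.zeros((2, 2, 2)))

    def test_single_mismatch_in_tiny_grid(self):
        g = np.zeros((2, 2, 2))
        p = g.copy()
        p[0, 0, 0] = 1.0
        assert re_mse(p, g) == pytest.approx(0.125)

    def test_re_mse_symmetry(self):
        p, g = random_pair(7)
        assert re_mse(p, g) == re_mse(g, p)


class TestEvaluate:
    def test_identical_volumes_score_perfectly(self):
        vol = np.zeros((10, 10, 10), bool)
        vol[2:8, 4:6, 4:6] = True
        rep = evaluate(vol, vol, (0.7, 0.7, 0.7))
        assert (rep.cl_dice, rep.dice, rep.iou) == (1.0, 1.0, 1.0)
        assert (rep.re_error, rep.chamfer_l2, rep.re_mse) == (0.0, 0.0, 0.0)

    def test_report_matches_individual_metrics(self):
        p, g = random_pair(21, p=0.4)
        g[3, 3, 3] = True
        spacing = (0.7, 0.7, 0.7)
        rep = evaluate(p, g, spacing)
        assert rep.dice == dice(p, g)
        assert rep.iou == iou(p, g)
        assert rep.cl_dice == cl_dice(p, g, spacing)
        assert rep.re_error == re_error(p, g)
        assert rep.re_mse == re_mse(p, g)
        assert rep.chamfer_l2 == pytest.approx(chamfer_l2(p, g, spacing), rel=1e-12)

    def test_dice_iou_identity_holds_in_every_report(self):
        for seed in range(10):
            p, g = random_pair(seed, p=0.4)
            g[2, 2, 2] = True
            rep = evaluate(p, g, (1, 1, 1))
            assert rep.dice == pytest.approx(2 * rep.iou / (1 + rep.iou))

    def test_summary_mean_std(self):
        reports = [
            MetricsReport(1.0, 1.0, 1.0, 0.0, 0.0, 0.0),
            MetricsReport(0.5, 0.5, 0.5, 0.2, 1.0, 0.01),
        ]
        summary = summarize_reports(reports)
        assert summary["dice"]["mean"] == pytest.approx(0.75)
        assert summary["dice"]["std"] == pytest.approx(0.25)
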