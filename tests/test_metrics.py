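"""Count metrics against per-pixel oracles, the Dice–Jaccard identity,
and the structure measure."""

import numpy as np
import pytest

from polypseg import (
    ConfusionCounts,
    confusion,
    dice_coefficient,
    evaluate_set,
    iou,
    mae,
    s_measure,
    sensitivity,
    specificity,
)


def brute_force_confusion(pred, gt):
    tp = fp = tn = fn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


class TestConfusion:
    def test_all_ones_pair(self):
        counts = confusion(np.ones((4, 4), int), np.ones((4, 4), int))
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (16, 0, 0, 0)

    def test_all_fp_pair(self):
        counts = confusion(np.ones((4, 4), int), np.zeros((4, 4), int))
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (0, 16, 0, 0)

    def test_matches_per_pixel_oracle(self, rng):
        for _ in range(50):
            pred = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
            gt = (rng.uniform(size=(16, 16)) > 0.7).astype(np.uint8)
            counts = confusion(pred, gt)
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == \
                brute_force_confusion(pred, gt)
            assert counts.total == 256

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 2), np.zeros((2, 2), int))


class TestCountMetrics:
    def test_worked_values(self):
        counts = ConfusionCounts(tp=50, fp=50, tn=0, fn=50)
        assert dice_coefficient(counts) == pytest.approx(0.5)
        assert iou(counts) == pytest.approx(1 / 3)
        assert sensitivity(ConfusionCounts(9, 0, 0, 1)) == pytest.approx(0.9)
        assert specificity(ConfusionCounts(0, 5, 95, 0)) == pytest.approx(0.95)

    def test_identical_masks_perfect_scores(self, rng):
        mask = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
        counts = confusion(mask, mask)
        assert dice_coefficient(counts) == 1.0
        assert iou(counts) == 1.0

    def test_disjoint_nonempty_masks_zero_dice(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice_coefficient(confusion(a, b)) == 0.0

    def test_degenerate_conventions(self):
        empty = ConfusionCounts(0, 0, 16, 0)
        assert dice_coefficient(empty) == 1.0
        assert iou(empty) == 1.0
        assert sensitivity(empty) == 1.0
        assert specificity(ConfusionCounts(16, 0, 0, 0)) == 1.0
        assert sensitivity(ConfusionCounts(0, 0, 0, 5)) == 0.0
        assert specificity(ConfusionCounts(0, 5, 0, 0)) == 0.0

    def test_dice_jaccard_identity(self, rng):
        """D = 2J / (1 + J) for every random fixture."""
        for _ in range(100):
            pred = (rng.uniform(size=(16, 16)) > rng.uniform()).astype(np.uint8)
            gt = (rng.uniform(size=(16, 16)) > rng.uniform()).astype(np.uint8)
            counts = confusion(pred, gt)
            d, j = dice_coefficient(counts), iou(counts)
            assert d == pytest.approx(2 * j / (1 + j))
            assert d >= j

    def test_transposition_invariance(self, rng):
        pred = (rng.uniform(size=(6, 9)) > 0.5).astype(np.uint8)
        gt = (rng.uniform(size=(6, 9)) > 0.5).astype(np.uint8)
        a, b = confusion(pred, gt), confusion(pred.T, gt.T)
        assert a == b
        assert mae(pred, gt) == mae(pred.T, gt.T)
        assert s_measure(pred.astype(float), gt) == pytest.approx(
            s_measure(pred.T.astype(float), gt.T)
        )


class TestSMeasure:
    def test_perfect_prediction_scores_one(self, rng):
        for _ in range(5):
            gt = np.zeros((12, 12), np.uint8)
            a, b = sorted(rng.integers(1, 11, 2))
            gt[a: b + 1, a: b + 1] = 1
            if gt.sum() in (0, gt.size):
                continue
            assert s_measure(gt.astype(float), gt) == pytest.approx(1.0)

    def test_inverted_half_plane_scores_low(self):
        gt = np.zeros((8, 8), np.uint8)
        gt[:, :4] = 1
        assert s_measure(1.0 - gt.astype(float), gt) <= 0.5

    def test_alpha_endpoints_select_components(self):
        gt = np.zeros((8, 8), np.uint8)
        gt[2:6, 2:6] = 1
        pred = np.full((8, 8), 0.4)
        s_obj = s_measure(pred, gt, alpha=1.0)
        s_reg = s_measure(pred, gt, alpha=0.0)
        mid = s_measure(pred, gt, alpha=0.5)
        assert mid == pytest.approx(0.5 * (s_obj + s_reg))

    def test_degenerate_ground_truths(self):
        pred = np.full((6, 6), 0.3)
        assert s_measure(pred, np.zeros((6, 6), np.uint8)) == pytest.approx(0.7)
        assert s_measure(pred, np.ones((6, 6), np.uint8)) == pytest.approx(0.3)

    def test_matches_direct_loop_oracle_on_fixture(self):
        """Cross-check against a literal, loop-based transcription of the
        structure-measure definition on one 8×8 fixture."""
        gt = np.zeros((8, 8), np.uint8)
        gt[1:5, 2:7] = 1
        pred = np.linspace(0, 1, 64).reshape(8, 8)

        eps = np.finfo(np.float64).eps
        # object term
        def obj(values):
            mu = values.mean()
            sd = values.std(ddof=1) if values.size > 1 else 0.0
            return 2 * mu / (mu * mu + 1 + sd + eps)

        gtb = gt.astype(bool)
        s_o = gtb.mean() * obj(pred[gtb]) + (1 - gtb.mean()) * obj(1 - pred[~gtb])
        # region term
        rows, cols = np.nonzero(gtb)
        ci, cj = int(round(rows.mean())), int(round(cols.mean()))
        s_r = 0.0
        for rs in (slice(0, ci + 1), slice(ci + 1, 8)):
            for cs in (slice(0, cj + 1), slice(cj + 1, 8)):
                p, g = pred[rs, cs].ravel(), gtb[rs, cs].astype(float).ravel()
                n = p.size
                x, y = p.mean(), g.mean()
                sx = ((p - x) ** 2).sum() / (n - 1)
                sy = ((g - y) ** 2).sum() / (n - 1)
                sxy = ((p - x) * (g - y)).sum() / (n - 1)
                a_, b_ = 4 * x * y * sxy, (x * x + y * y) * (sx + sy)
                q = a_ / (b_ + eps) if a_ != 0 else (1.0 if b_ == 0 else 0.0)
                s_r += (n / 64) * q
        expected = np.clip(0.5 * s_o + 0.5 * s_r, 0, 1)
        assert s_measure(pred, gt) == pytest.approx(float(expected), rel=1e-12)

    def test_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            s_measure(np.zeros((4, 4)), np.zeros((4, 4), np.uint8), alpha=1.5)


class TestMAE:
    def test_worked_values(self, rng):
        gt = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
        assert mae(gt.astype(float), gt) == 0.0
        assert mae(np.full((8, 8), 0.5), gt) == pytest.approx(0.5)
        assert mae(1.0 - gt.astype(float), gt) == pytest.approx(1.0)


class TestEvaluateSet:
    def test_single_perfect_pair(self):
        gt = np.zeros((8, 8), np.uint8)
        gt[2:6, 3:7] = 1
        report = evaluate_set([(gt.astype(float), gt)])
        assert (report.mdice, report.miou, report.sens,
                report.spe) == (1.0, 1.0, 1.0, 1.0)
        assert report.sm == pytest.approx(1.0)
        assert report.mae == 0.0
        assert report.n_images == 1

    def test_duplicated_pair_idempotent(self, rng):
        pred = rng.uniform(size=(8, 8))
        gt = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
        one = evaluate_set([(pred, gt)])
        two = evaluate_set([(pred, gt), (pred, gt)])
        assert one.mdice == two.mdice and one.sm == two.sm and one.mae == two.mae

    def test_two_pair_report_is_arithmetic_mean(self, rng):
        pairs = []
        for _ in range(2):
            pred = rng.uniform(size=(8, 8))
            gt = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
            pairs.append((pred, gt))
        singles = [evaluate_set([p]) for p in pairs]
        joint = evaluate_set(pairs)
        assert joint.mdice == pytest.approx(
            np.mean([s.mdice for s in singles]))
        assert joint.sm == pytest.approx(np.mean([s.sm for s in singles]))
        assert joint.mae == pytest.approx(np.mean([s.mae for s in singles]))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            evaluate_set([])
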