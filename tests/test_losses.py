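"""Dice, focal and compound loss: worked values, ranges, gradients."""

import itertools

import numpy as np
import pytest

from polypseg import LossConfig, Tensor, dice_loss, focal_loss, total_loss


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        mask = np.array([[1, 0], [1, 1]], dtype=np.float32)
        assert dice_loss(mask, mask, smooth=0.0).item() == pytest.approx(0.0)

    def test_disjoint_nonempty_is_one(self):
        a = np.array([[1, 0], [0, 0]], dtype=np.float32)
        b = np.array([[0, 0], [0, 1]], dtype=np.float32)
        assert dice_loss(a, b, smooth=0.0).item() == pytest.approx(1.0)

    def test_half_overlap_worked_example(self):
        # |X| = |Y| = 100, overlap 50 -> 1 - 100/200 = 0.5
        pred = np.zeros(300, dtype=np.float32)
        target = np.zeros(300, dtype=np.float32)
        pred[:100] = 1
        target[50:150] = 1
        assert dice_loss(pred, target, smooth=0.0).item() == pytest.approx(0.5)

    def test_exhaustive_2x2_range(self):
        """All 256 ordered pairs of binary 2×2 masks: loss stays in
        [0, 1]; max 1 only for disjoint non-empty pairs, min 0 for
        identical pairs (empty–empty convention gives 0)."""
        grids = [np.array(bits, dtype=np.float32).reshape(2, 2)
                 for bits in itertools.product((0, 1), repeat=4)]
        losses = {}
        for i, pred in enumerate(grids):
            for j, target in enumerate(grids):
                value = dice_loss(pred, target, smooth=0.0).item()
                losses[i, j] = value
                assert 0.0 <= value <= 1.0 + 1e-9
                inter = float((pred * target).sum())
                union_size = float(pred.sum() + target.sum())
                if union_size == 0:
                    assert value == pytest.approx(0.0)
                elif value >= 1.0 - 1e-9:
                    assert inter == 0 and union_size > 0
        assert max(losses.values()) == pytest.approx(1.0)
        assert min(losses.values()) == pytest.approx(0.0)

    def test_symmetric_for_binary_inputs(self, rng):
        a = (rng.uniform(size=(4, 4)) > 0.5).astype(np.float32)
        b = (rng.uniform(size=(4, 4)) > 0.5).astype(np.float32)
        assert dice_loss(a, b, smooth=0.0).item() == pytest.approx(
            dice_loss(b, a, smooth=0.0).item()
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((1, 4)), np.zeros((1, 5)))

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.uniform(0.1, 0.9, size=(1, 9)).astype(np.float32)
        target = (rng.uniform(size=(1, 9)) > 0.5).astype(np.float32)
        t = Tensor(pred.copy(), requires_grad=True)
        loss = dice_loss(t, target, smooth=1.0)
        loss.backward()
        eps = 1e-3
        for k in range(9):
            plus, minus = pred.copy(), pred.copy()
            plus[0, k] += eps
            minus[0, k] -= eps
            fd = (dice_loss(plus, target, smooth=1.0).item()
                  - dice_loss(minus, target, smooth=1.0).item()) / (2 * eps)
            assert t.grad[0, k] == pytest.approx(fd, abs=2e-3)


def _weighted_ce_oracle(pred, target, alpha):
    """Brute-force per-pixel α-balanced cross entropy."""
    p = np.clip(np.asarray(pred, dtype=np.float64), 1e-7, 1 - 1e-7)
    t = np.asarray(target, dtype=np.float64)
    return float(np.mean(-(alpha * t * np.log(p)
                           + (1 - alpha) * (1 - t) * np.log(1 - p))))


class TestFocalLoss:
    def test_perfect_prediction_vanishes(self):
        target = np.array([[1, 0, 1, 0]], dtype=np.float32)
        loss = focal_loss(target, target, LossConfig(focal_alpha=0.25,
                                                     focal_gamma=2.0))
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0])
    def test_gamma_zero_reduces_to_weighted_cross_entropy(self, rng, alpha):
        """Removing the focusing factor (γ=0) leaves the α-balanced
        cross entropy; checked against an independent oracle on random
        8×8 maps."""
        pred = rng.uniform(0.05, 0.95, size=(8, 8)).astype(np.float32)
        target = (rng.uniform(size=(8, 8)) > 0.6).astype(np.float32)
        ours = focal_loss(pred, target,
                          LossConfig(focal_alpha=alpha, focal_gamma=0.0))
        assert ours.item() == pytest.approx(
            _weighted_ce_oracle(pred, target, alpha), abs=1e-6
        )

    def test_gamma_zero_alpha_half_is_half_plain_bce(self, rng):
        pred = rng.uniform(0.05, 0.95, size=(8, 8)).astype(np.float32)
        target = (rng.uniform(size=(8, 8)) > 0.5).astype(np.float32)
        ours = focal_loss(pred, target,
                          LossConfig(focal_alpha=0.5, focal_gamma=0.0))
        p = np.clip(pred.astype(np.float64), 1e-7, 1 - 1e-7)
        bce = float(np.mean(-(target * np.log(p)
                              + (1 - target) * np.log(1 - p))))
        assert 2.0 * ours.item() == pytest.approx(bce, abs=1e-6)

    def test_single_foreground_pixel_worked_value(self):
        # one polyp pixel at p=0.5, α=0.25, γ=2: 0.25 · 0.25 · ln 2
        loss = focal_loss(np.array([[0.5]], dtype=np.float32),
                          np.array([[1.0]], dtype=np.float32),
                          LossConfig(focal_alpha=0.25, focal_gamma=2.0))
        assert loss.item() == pytest.approx(0.25 * 0.25 * np.log(2), rel=1e-5)

    def test_monotone_decreasing_in_p_t(self):
        values = [
            focal_loss(np.array([[p]], dtype=np.float32),
                       np.array([[1.0]], dtype=np.float32)).item()
            for p in np.linspace(0.05, 0.95, 10)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        cfg = LossConfig(focal_alpha=0.25, focal_gamma=2.0)
        pred = rng.uniform(0.2, 0.8, size=(1, 6)).astype(np.float64)
        target = (rng.uniform(size=(1, 6)) > 0.5).astype(np.float64)
        t = Tensor(pred, requires_grad=True)
        focal_loss(t, target, cfg).backward()
        eps = 1e-3
        for k in range(6):
            plus, minus = pred.copy(), pred.copy()
            plus[0, k] += eps
            minus[0, k] -= eps
            fd = (focal_loss(plus, target, cfg).item()
                  - focal_loss(minus, target, cfg).item()) / (2 * eps)
            assert t.grad[0, k] == pytest.approx(fd, abs=5e-3)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(focal_alpha=1.5)
        with pytest.raises(ValueError):
            LossConfig(focal_gamma=-1.0)


class TestTotalLoss:
    def test_perfect_prediction_near_zero(self):
        target = np.array([[1, 0], [0, 1]], dtype=np.float32)
        cfg = LossConfig(dice_smooth=0.0)
        assert total_loss(target, target, cfg).item() == pytest.approx(0.0, abs=1e-5)

    def test_additivity(self, rng):
        cfg = LossConfig()
        pred = rng.uniform(0.05, 0.95, size=(2, 16)).astype(np.float32)
        target = (rng.uniform(size=(2, 16)) > 0.5).astype(np.float32)
        total = total_loss(pred, target, cfg).item()
        parts = (dice_loss(pred, target, smooth=cfg.dice_smooth).item()
                 + focal_loss(pred, target, cfg).item())
        assert total == pytest.approx(parts, rel=1e-6)

    def test_dominates_each_component(self, rng):
        cfg = LossConfig()
        pred = rng.uniform(0.05, 0.95, size=(1, 25)).astype(np.float32)
        target = (rng.uniform(size=(1, 25)) > 0.5).astype(np.float32)
        total = total_loss(pred, target, cfg).item()
        assert total >= dice_loss(pred, target, smooth=cfg.dice_smooth).item()
        assert total >= focal_loss(pred, target, cfg).item()

    def test_component_weights_respected(self, rng):
        pred = rng.uniform(0.05, 0.95, size=(1, 9)).astype(np.float32)
        target = (rng.uniform(size=(1, 9)) > 0.5).astype(np.float32)
        cfg = LossConfig(dice_weight=2.0, focal_weight=0.5)
        expected = (2.0 * dice_loss(pred, target, smooth=cfg.dice_smooth).item()
                    + 0.5 * focal_loss(pred, target, cfg).item())
        assert total_loss(pred, target, cfg).item() == pytest.approx(expected, rel=1e-6)
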