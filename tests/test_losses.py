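"""Closed forms, oracles and gradient checks for every loss term."""

import numpy as np
import pytest

from shootcount.augmentation_masking import MaskSpec, random_patch_mask
from shootcount.autograd import Tensor
from shootcount.losses import (LossBreakdown, SSIMParams, classification_cross_entropy,
                               labeled_regression_loss, smooth_l1, ssim_score,
                               structural_loss, total_loss, tv_loss,
                               unsupervised_losses)
from shootcount.network import ModelOutput


def oracle_ssim(x, y, z1=0.01, z2=0.03, window=11, sigma=1.5):
    """Independent SSIM: explicit loops over valid window positions."""
    from scipy.signal.windows import gaussian
    h, w = x.shape
    size = min(window, h, w)
    if size % 2 == 0:
        size -= 1
    g = gaussian(size, std=sigma)
    k = np.outer(g, g)
    k /= k.sum()
    vals = []
    for i in range(h - size + 1):
        for j in range(w - size + 1):
            px = x[i:i + size, j:j + size]
            py = y[i:i + size, j:j + size]
            mx, my = (k * px).sum(), (k * py).sum()
            vx = (k * px * px).sum() - mx ** 2
            vy = (k * py * py).sum() - my ** 2
            cxy = (k * px * py).sum() - mx * my
            vals.append(((2 * mx * my + z1) * (2 * cxy + z2))
                        / ((mx ** 2 + my ** 2 + z1) * (vx + vy + z2)))
    return float(np.mean(vals))


class TestSSIM:
    def test_identity_is_exactly_one(self, rng):
        x = rng.random((12, 12))
        assert ssim_score(x, x).item() == pytest.approx(1.0, abs=1e-12)

    def test_constant_grids_closed_form(self):
        """X=0, Y=1: (0+Z1)(0+Z2) / ((1+Z1)(0+Z2)) = 0.01/1.01."""
        x, y = np.zeros((16, 16)), np.ones((16, 16))
        assert ssim_score(x, y).item() == pytest.approx(0.01 / 1.01, abs=1e-9)

    def test_symmetry(self, rng):
        x, y = rng.random((10, 10)), rng.random((10, 10))
        assert ssim_score(x, y).item() == pytest.approx(ssim_score(y, x).item(), abs=1e-12)

    def test_matches_windowed_oracle(self, rng):
        x, y = rng.random((14, 14)), rng.random((14, 14))
        assert ssim_score(x, y).item() == pytest.approx(oracle_ssim(x, y), abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_score(np.zeros((4, 4)), np.zeros((5, 5)))


class TestStructuralLoss:
    def test_perfect_prediction_gives_zero(self, rng):
        d = rng.random((8, 8))
        mask = (d > 1e-3).astype(float)
        assert structural_loss(d, d, mask).item() == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_mask_gives_zero(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert structural_loss(a, b, np.zeros((8, 8))).item() == pytest.approx(0.0, abs=1e-12)

    def test_matches_level_by_level_oracle(self, rng):
        """Pyramid oracle: mask, average-pool per level, SSIM via the
        windowed oracle, average the 1-SSIM terms."""
        a, b = rng.random((8, 8)), rng.random((8, 8))
        mask = (rng.random((8, 8)) > 0.3).astype(float)
        am, bm = a * mask, b * mask
        terms = []
        for level in range(3):
            if level > 0:
                am = am.reshape(am.shape[0] // 2, 2, -1, 2).mean(axis=(1, 3))
                bm = bm.reshape(bm.shape[0] // 2, 2, -1, 2).mean(axis=(1, 3))
            terms.append(1 - oracle_ssim(am, bm))
        expected = float(np.mean(terms))
        assert structural_loss(a, b, mask).item() == pytest.approx(expected, abs=1e-6)

    def test_bounded_between_zero_and_two(self, rng):
        for _ in range(5):
            a, b = rng.random((8, 8)), rng.random((8, 8))
            sl = structural_loss(a, b, np.ones((8, 8))).item()
            assert 0.0 <= sl <= 2.0

    def test_infeasible_pyramid_depth_rejected(self):
        with pytest.raises(ValueError):
            structural_loss(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)),
                            SSIMParams(k_levels=3))


class TestTVLoss:
    def test_scale_invariance(self, rng):
        gt = rng.random((8, 8))
        pred = rng.random((8, 8))
        a = tv_loss(pred, gt).item()
        b = tv_loss(pred * 7.3, gt).item()
        assert a == pytest.approx(b, rel=1e-9)

    def test_proportional_prediction_gives_zero(self, rng):
        gt = rng.random((8, 8))
        assert tv_loss(gt * 4.2, gt).item() == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_unit_masses(self):
        """gt and pred unit masses in different cells: 0.5 x 1 x 2 = 1."""
        gt = np.zeros((4, 4)); gt[0, 0] = 1.0
        pred = np.zeros((4, 4)); pred[3, 3] = 1.0
        assert tv_loss(pred, gt).item() == pytest.approx(1.0, abs=1e-9)

    def test_both_zero_is_zero(self):
        assert tv_loss(np.zeros((4, 4)), np.zeros((4, 4))).item() == pytest.approx(0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            tv_loss(np.full((4, 4), -1.0), np.ones((4, 4)))


class TestLabeledRegressionLoss:
    def test_perfect_prediction_is_zero(self, rng):
        d = rng.random((8, 8))
        assert labeled_regression_loss(d, d).item() == pytest.approx(0.0, abs=1e-12)

    def test_lambda_zero_reduces_to_structural(self, rng):
        pred, gt = rng.random((8, 8)), rng.random((8, 8))
        mask = (gt > 1e-3).astype(float)
        assert labeled_regression_loss(pred, gt, lambda1=0.0).item() == \
            pytest.approx(structural_loss(pred, gt, mask).item(), abs=1e-12)

    def test_component_sum(self, rng):
        pred, gt = rng.random((8, 8)), rng.random((8, 8))
        mask = (gt > 1e-3).astype(float)
        expected = structural_loss(pred, gt, mask).item() + 0.01 * tv_loss(pred, gt).item()
        assert labeled_regression_loss(pred, gt).item() == pytest.approx(expected, abs=1e-12)


class TestCrossEntropy:
    def test_confident_correct_prediction_is_zero(self):
        probs = np.array([[0.0, 1.0, 0.0]])
        assert classification_cross_entropy([1], probs).item() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_five_classes_is_ln5(self):
        probs = np.full((1, 5), 0.2)
        assert classification_cross_entropy([2], probs).item() == \
            pytest.approx(np.log(5), abs=1e-9)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            classification_cross_entropy([0], np.array([[0.5, 0.2]]))

    def test_zero_probability_is_floored_not_infinite(self):
        probs = np.array([[1.0, 0.0]])
        val = classification_cross_entropy([1], probs).item()
        assert np.isfinite(val) and val == pytest.approx(-np.log(1e-12))


class TestSmoothL1:
    @pytest.mark.parametrize("diff,expected", [(0.5, 0.125), (2.0, 1.5), (0.0, 0.0)])
    def test_branch_closed_forms(self, diff, expected):
        a = np.full((3, 3), diff)
        b = np.zeros((3, 3))
        assert smooth_l1(a, b, beta=1.0).item() == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            smooth_l1(np.zeros(3), np.zeros(4))


def _model_output(density, probs):
    d = Tensor(np.asarray(density, dtype=float))
    p = Tensor(np.asarray(probs, dtype=float))
    return ModelOutput(density=d, class_logits=p, class_probs=p)


class TestUnsupervisedLosses:
    def _mask(self, seed=0, ratio=0.25):
        return random_patch_mask(64, 64, MaskSpec(patch_size=16, ratio=ratio), seed=seed)

    def test_identical_student_teacher_is_zero(self, rng):
        d = rng.random((1, 1, 8, 8))
        p = np.full((1, 5), 0.2)
        l_ru, l_cu = unsupervised_losses(_model_output(d, p), _model_output(d, p),
                                         self._mask())
        assert l_ru.item() == 0.0 and l_cu.item() == 0.0

    def test_differences_outside_mask_are_invisible(self, rng):
        """L_RU only sees the masked-patch footprint at 1/8 scale."""
        mask = self._mask(seed=3)
        foot = mask.pixel_mask.reshape(8, 8, 8, 8).max(axis=(1, 3)).astype(bool)
        teacher = rng.random((1, 1, 8, 8))
        student = teacher.copy()
        student[0, 0][~foot] += 5.0  # perturb only outside the footprint
        p = np.full((1, 5), 0.2)
        l_ru, _ = unsupervised_losses(_model_output(student, p),
                                      _model_output(teacher, p), mask)
        assert l_ru.item() == pytest.approx(0.0, abs=1e-12)

    def test_single_patch_constant_discrepancy_oracle(self):
        """One masked 16x16 patch = 2x2 density cells; unit discrepancy in the
        quadratic... no — |d|=1 is the boundary, linear branch: 1 - 0.5 = 0.5."""
        grid = np.zeros((4, 4), dtype=bool)
        grid[1, 2] = True
        from shootcount.augmentation_masking import PatchMask
        mask = PatchMask(grid=grid, patch_size=16)
        teacher = np.zeros((1, 1, 8, 8))
        student = np.ones((1, 1, 8, 8))
        p = np.full((1, 5), 0.2)
        l_ru, _ = unsupervised_losses(_model_output(student, p),
                                      _model_output(teacher, p), mask)
        assert l_ru.item() == pytest.approx(0.5, abs=1e-12)

    def test_empty_mask_with_positive_ratio_errors(self, rng):
        mask = self._mask(ratio=0.0)
        d = rng.random((1, 1, 8, 8))
        p = np.full((1, 5), 0.2)
        with pytest.raises(ValueError, match="empty mask"):
            unsupervised_losses(_model_output(d, p), _model_output(d, p), mask)

    def test_no_gradient_reaches_the_teacher(self, rng):
        mask = self._mask()
        t_density = Tensor(rng.random((1, 1, 8, 8)), requires_grad=True)
        s_density = Tensor(rng.random((1, 1, 8, 8)), requires_grad=True)
        p = Tensor(np.full((1, 5), 0.2), requires_grad=True)
        student = ModelOutput(density=s_density, class_logits=p, class_probs=p)
        teacher = ModelOutput(density=t_density, class_logits=p, class_probs=p)
        l_ru, _ = unsupervised_losses(student, teacher, mask)
        l_ru.backward()
        assert t_density.grad is None
        assert s_density.grad is not None


class TestTotalLoss:
    def test_breakdown_arithmetic(self):
        bd = total_loss(1.0, 2.0, 3.0, 4.0)
        assert bd.l_l == 3.0 and bd.l_u == 7.0 and bd.total == 10.0

    def test_all_zero(self):
        assert total_loss(0.0, 0.0, 0.0, 0.0).total == 0.0

    def test_nan_aborts_with_component_name(self):
        with pytest.raises(FloatingPointError, match="l_ru"):
            total_loss(1.0, 1.0, np.nan, 1.0)


class TestLossGradients:
    """Analytic gradients vs central finite differences on random 8x8 maps."""

    @staticmethod
    def fd_grad(fn, x, eps=1e-6):
        num = np.zeros_like(x.data)
        it = np.nditer(x.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = x.data[i]
            x.data[i] = orig + eps
            f1 = fn().item()
            x.data[i] = orig - eps
            f0 = fn().item()
            x.data[i] = orig
            num[i] = (f1 - f0) / (2 * eps)
        return num

    def test_structural_loss_gradient(self, rng):
        pred = Tensor(rng.random((8, 8)) + 0.1, requires_grad=True)
        gt = rng.random((8, 8))
        mask = np.ones((8, 8))
        fn = lambda: structural_loss(pred, gt, mask)
        fn().backward()
        np.testing.assert_allclose(pred.grad, self.fd_grad(fn, pred), atol=1e-4)

    def test_tv_loss_gradient(self, rng):
        pred = Tensor(rng.random((8, 8)) + 0.5, requires_grad=True)
        gt = rng.random((8, 8))
        fn = lambda: tv_loss(pred, gt)
        fn().backward()
        np.testing.assert_allclose(pred.grad, self.fd_grad(fn, pred), atol=1e-4)

    def test_cross_entropy_gradient(self, rng):
        raw = rng.random((2, 5)) + 0.2
        probs = Tensor(raw / raw.sum(axis=1, keepdims=True), requires_grad=True)
        fn = lambda: classification_cross_entropy([1, 3], probs)
        fn().backward()
        np.testing.assert_allclose(probs.grad, self.fd_grad(fn, probs), atol=1e-4)

    def test_smooth_l1_gradient_spans_both_branches(self, rng):
        a = Tensor(rng.uniform(-2, 2, size=(6, 6)), requires_grad=True)
        b = np.zeros((6, 6))
        fn = lambda: smooth_l1(a, b)
        fn().backward()
        np.testing.assert_allclose(a.grad, self.fd_grad(fn, a), atol=1e-4)
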