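"""Dice / MSE / NCC metrics, training losses, and pair evaluation."""

import numpy as np
import pytest

from udrnet import (DeformSpec, DisplacementField, LossConfig, Mask,
                    NetworkConfig, PhantomSpec, RegistrationModel, Volume,
                    dice, evaluate_pair, make_pair, mse, ncc, similarity_loss,
                    smoothness_loss)
from udrnet._autodiff import Tensor
from udrnet.core_io import ImagePair, IntensityDomain


def _vol(data):
    return Volume(np.asarray(data, np.float32),
                  intensity_domain=IntensityDomain.NORMALIZED_0_1)


def _loop_dice(a, b):
    inter = na = nb = 0
    for z in range(a.shape[0]):
        for y in range(a.shape[1]):
            for x in range(a.shape[2]):
                na += int(a[z, y, x])
                nb += int(b[z, y, x])
                inter += int(a[z, y, x]) * int(b[z, y, x])
    return 2 * inter / (na + nb) if na + nb else 1.0


def _loop_mse(f, m):
    s = 0.0
    n = 0
    for z in range(f.shape[0]):
        for y in range(f.shape[1]):
            for x in range(f.shape[2]):
                s += (float(f[z, y, x]) - float(m[z, y, x])) ** 2
                n += 1
    return s / n


def _loop_ncc(f, m):
    vals_f = [float(v) for v in f.ravel()]
    vals_m = [float(v) for v in m.ravel()]
    mu_f = sum(vals_f) / len(vals_f)
    mu_m = sum(vals_m) / len(vals_m)
    num = sum((a - mu_f) * (b - mu_m) for a, b in zip(vals_f, vals_m))
    den = (sum((a - mu_f) ** 2 for a in vals_f)
           * sum((b - mu_m) ** 2 for b in vals_m)) ** 0.5
    return num / den


class TestOracles:
    def test_metrics_match_scalar_loops_on_random_volumes(self, rng):
        for _ in range(20):
            f = rng.uniform(0, 1, size=(8, 8, 8)).astype(np.float32)
            m = rng.uniform(0, 1, size=(8, 8, 8)).astype(np.float32)
            a = (rng.uniform(size=(8, 8, 8)) > 0.5).astype(np.uint8)
            b = (rng.uniform(size=(8, 8, 8)) > 0.5).astype(np.uint8)
            assert mse(_vol(f), _vol(m)) == pytest.approx(_loop_mse(f, m), abs=1e-6)
            assert ncc(_vol(f), _vol(m)) == pytest.approx(_loop_ncc(f, m), abs=1e-6)
            assert dice(Mask(a), Mask(b)) == pytest.approx(_loop_dice(a, b), abs=1e-6)


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((2, 2, 2), np.uint8)
        a[0] = 1
        assert dice(Mask(a), Mask(a)) == 1.0
        assert dice(Mask(a), Mask(1 - a)) == 0.0

    def test_hand_counted_example(self):
        """|A| = |B| = 3, |A∩B| = 2 -> 2*2/6."""
        a = np.zeros((2, 2, 2), np.uint8)
        b = np.zeros((2, 2, 2), np.uint8)
        a.ravel()[[0, 1, 2]] = 1
        b.ravel()[[1, 2, 5]] = 1
        assert dice(Mask(a), Mask(b)) == pytest.approx(2 / 3, abs=1e-9)

    def test_empty_masks_define_perfect_agreement(self):
        z = Mask(np.zeros((2, 2, 2), np.uint8))
        assert dice(z, z) == 1.0

    def test_symmetry(self, rng):
        a = Mask((rng.uniform(size=(4, 4, 4)) > 0.4).astype(np.uint8))
        b = Mask((rng.uniform(size=(4, 4, 4)) > 0.6).astype(np.uint8))
        assert dice(a, b) == dice(b, a)


class TestMse:
    def test_identical_zero_and_unit_extremes(self):
        f = _vol(np.ones((2, 2, 2)))
        assert mse(f, f) == 0.0
        assert mse(f, _vol(np.zeros((2, 2, 2)))) == 1.0

    def test_two_voxel_hand_example(self):
        f = _vol(np.array([0.0, 0.5]).reshape(1, 1, 2))
        m = _vol(np.array([0.5, 0.5]).reshape(1, 1, 2))
        assert mse(f, m) == pytest.approx(0.125, abs=1e-9)


class TestNcc:
    def test_perfect_anti_and_affine_invariance(self, rng):
        f = rng.uniform(0, 1, size=(6, 6, 6))
        v = Volume(f)
        assert ncc(v, Volume(f.copy())) == pytest.approx(1.0, abs=1e-9)
        assert ncc(v, Volume(-f + 0.7)) == pytest.approx(-1.0, abs=1e-9)
        assert ncc(v, Volume(2 * f + 3)) == pytest.approx(1.0, abs=1e-9)
        assert ncc(v, Volume(-2 * f + 3)) == pytest.approx(-1.0, abs=1e-9)

    def test_symmetry(self, rng):
        f = Volume(rng.uniform(size=(5, 5, 5)))
        m = Volume(rng.uniform(size=(5, 5, 5)))
        assert ncc(f, m) == pytest.approx(ncc(m, f), abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            ncc(Volume(np.ones((3, 3, 3))), Volume(np.arange(27.0).reshape(3, 3, 3)))


class TestSimilarityLoss:
    def test_zero_at_alignment_for_both_options(self, rng):
        f = rng.uniform(0, 1, size=(6, 6, 6)).astype(np.float32)
        assert float(similarity_loss(f, f, LossConfig("mse")).data) == 0.0
        assert float(similarity_loss(f, f, LossConfig("ncc")).data) == pytest.approx(
            0.0, abs=1e-6)

    def test_nonnegative_and_anticorrelated_ncc_is_two(self, rng):
        f = rng.uniform(0, 1, size=(6, 6, 6)).astype(np.float32)
        w = rng.uniform(0, 1, size=(6, 6, 6)).astype(np.float32)
        assert float(similarity_loss(f, w, LossConfig("mse")).data) >= 0
        assert float(similarity_loss(f, w, LossConfig("ncc")).data) >= 0
        anti = (-f + 1.0).astype(np.float32)
        assert float(similarity_loss(f, anti, LossConfig("ncc")).data) == pytest.approx(
            2.0, abs=1e-5)

    def test_differentiable_wrt_warped(self, rng):
        f = rng.uniform(0, 1, size=(4, 4, 4)).astype(np.float32)
        w = Tensor(rng.uniform(0, 1, size=(4, 4, 4)).astype(np.float32),
                   requires_grad=True)
        similarity_loss(f, w, LossConfig("ncc")).backward()
        assert np.all(np.isfinite(w.grad)) and np.abs(w.grad).max() > 0


class TestSmoothnessLoss:
    def test_constant_field_has_zero_penalty(self):
        d = np.zeros((3, 4, 4, 4), np.float32)
        assert float(smoothness_loss(DisplacementField(d)).data) == 0.0
        d[:] = 3.5  # pure translation
        assert float(smoothness_loss(DisplacementField(d)).data) == 0.0

    def test_unit_ramp_contributes_unit_gradient(self):
        """One component a slope-1 ramp along one axis: every forward
        difference along that axis is 1, others 0, so the penalty is the
        mean over components/axes of those squares."""
        d = np.zeros((3, 4, 4, 4), np.float32)
        d[0] = np.arange(4, dtype=np.float32)[:, None, None]
        val = float(smoothness_loss(DisplacementField(d)).data)
        # axis 0 of component 0 contributes mean 1 over (1/3 of components);
        # the implementation averages per axis over all components
        assert val == pytest.approx(1.0 / 3.0, abs=1e-6)


class TestEvaluatePair:
    def test_aligned_pair_scores_perfect(self, rng):
        model = RegistrationModel(NetworkConfig(levels=2, enc_channels=(2, 4),
                                                dec_channels=(4, 2),
                                                prehead_channels=2))
        pair = make_pair(PhantomSpec(shape=(16, 16, 16), seed=3),
                         DeformSpec(max_displacement=0.0, smoothness_sigma=4.0))
        assert np.array_equal(pair.fixed.data, pair.moving.data)
        rep = evaluate_pair(model, pair)
        assert rep.one_minus_mse_pct == pytest.approx(100.0, abs=1e-6)
        assert rep.ncc_pct == pytest.approx(100.0, abs=1e-4)
        assert rep.dice_pct == pytest.approx(100.0, abs=1e-9)

    def test_missing_masks_report_absent_dice(self, rng, tiny_model, tiny_pair):
        pair = ImagePair(fixed=tiny_pair.fixed, moving=tiny_pair.moving)
        rep = evaluate_pair(tiny_model, pair)
        assert rep.dice_pct is None
        assert np.isfinite(rep.ncc_pct)

    def test_true_field_recovers_perfect_alignment(self, tiny_pair):
        """Warping the moving image with the stored ground-truth field must
        reproduce the fixed image exactly — this pins the pull-warp
        direction convention."""
        from udrnet import warp_image, warp_mask
        warped = warp_image(tiny_pair.moving, tiny_pair.true_dvf)
        assert np.array_equal(warped.data, tiny_pair.fixed.data)
        d = dice(tiny_pair.fixed_mask,
                 warp_mask(tiny_pair.moving_mask, tiny_pair.true_dvf))
        assert d == 1.0
        pre = dice(tiny_pair.fixed_mask, tiny_pair.moving_mask)
        assert pre < 1.0  # the deformation actually moved the mask
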