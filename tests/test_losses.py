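import numpy as np
import pytest
from skimage.metrics import structural_similarity

from endosfm.autodiff import Tensor
from endosfm.geometry import WarpResult
from endosfm.losses import (LossWeights, data_fidelity, depth_consistency,
                            edge_aware_smoothness, photometric,
                            residual_smoothness, ssim, total_loss)

from oracles import (data_fidelity_scalar, edge_smoothness_scalar,
                     photometric_scalar, residual_smoothness_scalar,
                     ssim_scalar)


def chw(img):
    """(H, W, C) -> (1, C, H, W)."""
    return np.asarray(img, float).transpose(2, 0, 1)[None]


class TestIdentities:
    def test_photometric_of_identical_images_is_zero(self, rng):
        img = rng.random((1, 3, 8, 8))
        assert photometric(img, img).data == pytest.approx(0.0, abs=1e-12)

    def test_data_fidelity_zero_for_perfect_warp(self, rng):
        img = rng.random((1, 3, 8, 8))
        calib = np.zeros_like(img)
        val = data_fidelity(img, img, calib=calib).item()
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_residual_smoothness_zero_for_constant_calib(self, rng):
        calib = np.full((1, 3, 8, 8), 0.2)
        target = rng.random((1, 3, 8, 8))
        warped = rng.random((1, 3, 8, 8))
        assert residual_smoothness(calib, target, warped).item() == 0.0

    def test_edge_smoothness_zero_for_constant_disparity(self, rng):
        disp = np.full((1, 1, 8, 8), 0.7)
        target = rng.random((1, 3, 8, 8))
        assert edge_aware_smoothness(disp, target).item() == 0.0

    def test_depth_consistency_zero_for_equal_depths(self, rng):
        d = 1.0 + rng.random((1, 1, 8, 8))
        assert depth_consistency(d, d).item() == 0.0


class TestSSIM:
    def test_matches_scalar_oracle(self, rng):
        a = rng.random((6, 7))
        b = rng.random((6, 7))
        out = ssim(a[None, None], b[None, None]).data[0, 0]
        assert np.abs(out - ssim_scalar(a, b)).max() < 1e-12

    def test_interior_matches_skimage(self, rng):
        """Away from borders the clipped window equals skimage's full
        window, so the two implementations must agree there."""
        a = rng.random((16, 16))
        b = np.clip(a + 0.05 * rng.normal(size=(16, 16)), 0, 1)
        _, smap = structural_similarity(
            a, b, win_size=3, data_range=1.0, full=True,
            use_sample_covariance=False, gaussian_weights=False)
        ours = ssim(a[None, None], b[None, None]).data[0, 0]
        assert np.allclose(ours[1:-1, 1:-1], smap[1:-1, 1:-1], atol=1e-10)

    def test_self_similarity_is_one(self, rng):
        a = rng.random((5, 5))
        assert np.allclose(ssim(a[None, None], a[None, None]).data, 1.0)


class TestScalarOracles:
    def test_photometric_matches_oracle(self, rng):
        a = rng.random((8, 8, 3))
        b = rng.random((8, 8, 3))
        out = photometric(chw(a), chw(b)).data[0, 0]
        assert np.abs(out - photometric_scalar(a, b)).max() < 1e-6

    def test_data_fidelity_matches_oracle(self, rng):
        warped = rng.random((8, 8, 3))
        target = rng.random((8, 8, 3))
        calib = 0.1 * rng.normal(size=(8, 8, 3))
        vis = (rng.random((8, 8)) > 0.3).astype(float)
        ours = data_fidelity(chw(warped), chw(target), calib=chw(calib),
                             vis=vis[None, None]).item()
        ref = data_fidelity_scalar(warped, target, calib, vis)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_residual_smoothness_matches_oracle(self, rng):
        calib = 0.2 * rng.normal(size=(8, 8, 3))
        target = rng.random((8, 8, 3))
        warped = rng.random((8, 8, 3))
        ours = residual_smoothness(chw(calib), chw(target),
                                   chw(warped)).item()
        ref = residual_smoothness_scalar(calib, target, warped)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_edge_smoothness_matches_oracle(self, rng):
        disp = 0.2 + 0.6 * rng.random((8, 8))
        target = rng.random((8, 8, 3))
        ours = edge_aware_smoothness(disp[None, None], chw(target)).item()
        ref = edge_smoothness_scalar(disp, target)
        assert ours == pytest.approx(ref, abs=1e-6)


class TestMasking:
    def test_invalid_pixels_cannot_lower_the_loss(self, rng):
        """Shrinking the valid mask must not reduce the photometric term:
        the loss averages over retained pixels, so discarding pixels of a
        uniform-error image leaves it unchanged."""
        target = rng.random((8, 8, 3))
        warped = np.clip(target + 0.1, 0, 1)
        full = np.ones((8, 8))
        partial = np.ones((8, 8))
        partial[:, 5:] = 0.0
        l_full = data_fidelity((chw(warped), full[None]), chw(target)).item()
        l_part = data_fidelity((chw(warped) * partial[None, None],
                                partial[None]), chw(target)).item()
        assert l_part >= l_full - 1e-9

    def test_mask_erosion_blocks_ssim_contamination(self, rng):
        """Zeros behind the invalid region must not leak into the retained
        pixels through the 3x3 SSIM window."""
        target = rng.random((8, 8, 3))
        warped = target.copy()
        warped[:, 5:] = 0.0              # arbitrary fill behind the mask
        mask = np.ones((8, 8))
        mask[:, 5:] = 0.0
        val = data_fidelity((chw(warped), mask[None]), chw(target)).item()
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_empty_mask_warns_and_returns_zero(self, rng):
        target = rng.random((4, 4, 3))
        with pytest.warns(RuntimeWarning):
            val = data_fidelity((chw(target), np.zeros((1, 4, 4))),
                                chw(target)).item()
        assert val == 0.0

    def test_list_of_sources_is_averaged(self, rng):
        target = rng.random((8, 8, 3))
        w1 = rng.random((8, 8, 3))
        w2 = rng.random((8, 8, 3))
        single1 = data_fidelity(chw(w1), chw(target)).item()
        single2 = data_fidelity(chw(w2), chw(target)).item()
        both = data_fidelity([chw(w1), chw(w2)], chw(target)).item()
        assert both == pytest.approx((single1 + single2) / 2, abs=1e-12)

    def test_warp_result_object_accepted(self, rng):
        target = rng.random((8, 8, 3))
        res = WarpResult(image=chw(target), valid_mask=np.ones((1, 8, 8)))
        assert data_fidelity(res, chw(target)).item() == pytest.approx(0.0)


class TestTotalLoss:
    def test_weighted_combination(self):
        w = LossWeights(alpha=0.85, kappa=2.0, lambda1=0.01, lambda2=0.001,
                        lambda3=0.0001)
        bd = total_loss(1.0, 2.0, 3.0, 4.0, 5.0, w, consistency_weight=0.05)
        expected = 1.0 + 2.0 * (0.01 * 2.0 + 0.001 * 3.0 + 0.0001 * 4.0) \
            + 0.05 * 5.0
        assert bd.total == pytest.approx(expected)

    def test_non_finite_term_raises_with_name(self):
        with pytest.raises(FloatingPointError, match="auxiliary"):
            total_loss(1.0, 2.0, np.nan, 4.0, 5.0, LossWeights())

    def test_total_is_tensor_when_inputs_are(self):
        bd = total_loss(Tensor(1.0), 0.0, 0.0, 0.0, 0.0, LossWeights())
        assert isinstance(bd.total, Tensor)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=1.5)
        with pytest.raises(ValueError):
            LossWeights(kappa=-1.0)


class TestDepthConsistency:
    def test_symmetry_and_bounds(self, rng):
        a = 0.5 + rng.random((1, 1, 6, 6))
        b = 0.5 + rng.random((1, 1, 6, 6))
        ab = depth_consistency(a, b).item()
        ba = depth_consistency(b, a).item()
        assert ab == pytest.approx(ba, abs=1e-12)
        assert 0.0 <= ab < 1.0

    def test_scale_robustness(self, rng):
        """mean |a-b|/(a+b) is invariant to a common scale."""
        a = 0.5 + rng.random((1, 1, 6, 6))
        b = 0.5 + rng.random((1, 1, 6, 6))
        assert depth_consistency(3 * a, 3 * b).item() == pytest.approx(
            depth_consistency(a, b).item(), abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            depth_consistency(np.zeros((1, 1, 2, 2)), np.ones((1, 1, 2, 2)))
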