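"""Region-restricted MSE/RMSE/PSNR/SSIM against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctinpaint import (
    CTSlice,
    PhantomSpec,
    SSIMConstants,
    apply_mask,
    evaluate_pair,
    make_truncation_mask,
    mse_rmse,
    psnr,
    ssim,
)
from ctinpaint.phantom import generate_phantom

GLOBAL = SSIMConstants(mode="global")


def _loop_mse(x, y, region):
    acc, n = 0.0, 0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            if region[i, j]:
                acc += (x[i, j] - y[i, j]) ** 2
                n += 1
    return acc / n


class TestMseRmse:
    def test_identical_images(self):
        x = np.random.default_rng(0).integers(0, 256, (16, 16)).astype(float)
        assert mse_rmse(x, x) == (0.0, 0.0)

    def test_constant_offset(self):
        x = np.random.default_rng(1).integers(0, 200, (16, 16)).astype(float)
        assert mse_rmse(x, x + 3.0) == pytest.approx((9.0, 3.0))

    def test_loop_oracle_on_100_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.integers(0, 256, (8, 8)).astype(float)
            y = rng.integers(0, 256, (8, 8)).astype(float)
            region = rng.random((8, 8)) > 0.3
            if not region.any():
                region[0, 0] = True
            mse, rmse = mse_rmse(x, y, region)
            ref = _loop_mse(x, y, region)
            assert abs(mse - ref) < 1e-10
            assert abs(rmse - math.sqrt(ref)) < 1e-10

    def test_empty_region_raises(self):
        x = np.zeros((4, 4))
        with pytest.raises(ValueError, match="empty"):
            mse_rmse(x, x, np.zeros((4, 4), dtype=bool))

    @given(seed=st.integers(0, 2**16))
    def test_rmse_triangle_bound(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = (rng.integers(0, 256, (8, 8)).astype(float) for _ in range(3))
        _, rxz = mse_rmse(x, z)
        _, rxy = mse_rmse(x, y)
        _, ryz = mse_rmse(y, z)
        assert rxz <= rxy + ryz + 1e-12


class TestPsnr:
    def test_mse_equal_to_s_squared_gives_zero_db(self):
        x = np.zeros((8, 8))
        y = np.full((8, 8), 255.0)
        assert psnr(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_one_level_difference(self):
        x = np.full((8, 8), 100.0)
        assert psnr(x, x + 1.0) == pytest.approx(20 * math.log10(255), rel=1e-12)

    def test_identical_images_flagged_infinite(self):
        x = np.random.default_rng(3).integers(0, 256, (8, 8)).astype(float)
        assert math.isinf(psnr(x, x))

    def test_strictly_decreasing_in_mse(self):
        x = np.full((16, 16), 90.0)
        values = [psnr(x, x + d) for d in (1.0, 2.0, 5.0, 11.0, 40.0)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSsim:
    def test_identity_is_one(self):
        x = np.random.default_rng(4).integers(0, 256, (32, 32)).astype(float)
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)
        assert ssim(x, x, consts=GLOBAL) == pytest.approx(1.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        a, b = 60.0, 200.0
        x = np.full((16, 16), a)
        y = np.full((16, 16), b)
        c1 = (0.01 * 255) ** 2
        expected = (2 * a * b + c1) / (a * a + b * b + c1)
        assert ssim(x, y, consts=GLOBAL) == pytest.approx(expected, rel=1e-12)
        # windowed and global agree on constant-statistics images
        assert ssim(x, y) == pytest.approx(expected, rel=1e-12)

    def test_global_mode_matches_moment_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.integers(0, 256, (8, 8)).astype(float)
            y = rng.integers(0, 256, (8, 8)).astype(float)
            mx, my = x.mean(), y.mean()
            vx, vy = x.var(), y.var()
            cov = ((x - mx) * (y - my)).mean()
            c1, c2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
            expected = ((2 * mx * my + c1) * (2 * cov + c2)) / (
                (mx**2 + my**2 + c1) * (vx + vy + c2))
            assert ssim(x, y, consts=GLOBAL) == pytest.approx(expected, abs=1e-10)

    def test_windowed_matches_skimage(self):
        from skimage.metrics import structural_similarity

        sl, _ = generate_phantom(PhantomSpec(seed=30))
        other, _ = generate_phantom(PhantomSpec(seed=31))
        x = sl.pixels.astype(float)
        y = other.pixels.astype(float)
        ref = structural_similarity(x, y, data_range=255, gaussian_weights=True,
                                    sigma=1.5, use_sample_covariance=False)
        assert ssim(x, y) == pytest.approx(ref, abs=1e-10)

    @given(seed=st.integers(0, 2**16))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 256, (16, 16)).astype(float)
        y = rng.integers(0, 256, (16, 16)).astype(float)
        assert abs(ssim(x, y) - ssim(y, x)) < 1e-12

    def test_small_region_falls_back_to_global(self):
        x = np.random.default_rng(6).integers(0, 256, (8, 8)).astype(float)
        y = x + 5.0
        with pytest.warns(UserWarning, match="global"):
            windowed = ssim(x, y)
        assert windowed == pytest.approx(ssim(x, y, consts=GLOBAL))


class TestEvaluatePair:
    def test_perfect_output_both_regions(self):
        sl, _ = generate_phantom(PhantomSpec(seed=40))
        mask = make_truncation_mask(128, 36, 36)
        whole, gen = evaluate_pair(sl, sl, mask)
        assert whole.ssim == pytest.approx(1.0) and gen.ssim == pytest.approx(1.0)
        assert whole.rmse == 0.0 and gen.rmse == 0.0
        assert whole.psnr_is_infinite and gen.psnr_is_infinite

    def test_zero_filled_input_ranks_regions(self):
        sl, _ = generate_phantom(PhantomSpec(seed=41))
        mask = make_truncation_mask(128, 36, 36)
        whole, gen = evaluate_pair(sl, apply_mask(sl, mask), mask)
        assert whole.ssim > gen.ssim  # known region is perfect
        assert gen.n_pixels == 9216
        assert whole.n_pixels == 128 * 128

    def test_all_known_mask_flags_empty_generation_report(self):
        sl, _ = generate_phantom(PhantomSpec(seed=42))
        mask = make_truncation_mask(128, 0, 0)
        _, gen = evaluate_pair(sl, sl, mask)
        assert gen.empty and gen.n_pixels == 0
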