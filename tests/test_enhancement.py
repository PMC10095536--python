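"""AHE-Retinex enhancement: conversions, retinex maps, colour restoration."""

import numpy as np
import pytest

from leukoseg.enhancement import (RetinexConfig, adaptive_hist_eq, ahe_retinex,
                                  color_restoration, gaussian_surround,
                                  hsv_to_rgb, msr, msrcr, rgb_to_hsv, ssr)


class TestColorConversion:
    def test_pure_red_anchor(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 0)
        h, s, v = rgb_to_hsv(img)[0, 0]
        assert h == pytest.approx(0.0)
        assert s == pytest.approx(1.0)
        assert v == pytest.approx(1.0)

    def test_gray_is_achromatic(self):
        img = np.full((2, 2, 3), 128, dtype=np.uint8)
        hsv = rgb_to_hsv(img)
        np.testing.assert_allclose(hsv[..., 1], 0.0)
        np.testing.assert_allclose(hsv[..., 2], 128 / 255.0)

    def test_round_trip_within_one_level(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        back = hsv_to_rgb(rgb_to_hsv(img))
        assert np.abs(back.astype(int) - img.astype(int)).max() <= 1

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            rgb_to_hsv(np.zeros((4, 4)))


class TestAdaptiveHistEq:
    def test_constant_image_unchanged(self):
        v = np.full((32, 32), 100, dtype=np.uint8)
        np.testing.assert_array_equal(adaptive_hist_eq(v), v)

    def test_two_level_populations_stay_distinct(self):
        v = np.full((32, 32), 40, dtype=np.uint8)
        v[:, 16:] = 200
        out = adaptive_hist_eq(v, tile_grid=(2, 2))
        lo, hi = out[:, :8].astype(float).mean(), out[:, 24:].astype(float).mean()
        assert hi - lo >= 160  # dynamic range not reduced

    def test_low_contrast_ramp_gains_contrast(self):
        ramp = np.linspace(100, 140, 64)[None].repeat(64, axis=0).astype(np.uint8)
        out = adaptive_hist_eq(ramp)
        assert out.astype(float).std() > ramp.astype(float).std()

    def test_oversized_tile_grid_rejected(self):
        with pytest.raises(ValueError):
            adaptive_hist_eq(np.zeros((8, 8), dtype=np.uint8), tile_grid=(16, 16))


class TestGaussianSurround:
    @pytest.mark.parametrize("scale,size", [(1.5, 9), (15.0, 101), (80.0, 51)])
    def test_normalized(self, scale, size):
        assert gaussian_surround(scale, size).sum() == pytest.approx(1.0, abs=1e-9)

    def test_small_scale_approaches_impulse(self):
        k = gaussian_surround(1e-3, 3)
        assert k[1, 1] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_with_central_peak(self):
        k = gaussian_surround(15.0, 101)
        assert k[50, 50] == k.max()
        np.testing.assert_allclose(k, np.rot90(k), atol=1e-15)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            gaussian_surround(-1.0, 9)


class TestRetinex:
    def test_ssr_constant_channel_is_zero_map(self):
        r = ssr(np.full((16, 16), 128.0), scale=15.0)
        assert np.abs(r).max() < 1e-9

    def test_ssr_sign_structure_around_bright_pixel(self):
        ch = np.zeros((21, 21))
        ch[10, 10] = 200.0
        r = ssr(ch, scale=3.0)
        assert r[10, 10] > 0
        assert r[10, 12] < 0  # surround of the peak

    def test_ssr_matches_brute_force_convolution(self, rng):
        ch = rng.uniform(0, 255, (16, 16))
        scale = 5.0
        ks = 2 * int(np.ceil(3 * scale)) + 1
        kernel = gaussian_surround(scale, ks)
        pad = ks // 2
        xp = np.pad(ch, pad, mode="symmetric")
        blur = np.empty((16, 16))
        for i in range(16):
            for j in range(16):
                blur[i, j] = (xp[i:i + ks, j:j + ks] * kernel).sum()
        oracle = np.log(ch + 1.0) - np.log(blur + 1.0)
        np.testing.assert_allclose(ssr(ch, scale), oracle, atol=1e-8)

    def test_msr_weight_collapse_equals_ssr(self, rng):
        ch = rng.uniform(0, 255, (12, 12))
        cfg = RetinexConfig(scales=(5.0, 15.0, 40.0), scale_weights=(1.0, 0.0, 0.0))
        np.testing.assert_array_equal(msr(ch, cfg), ssr(ch, 5.0))

    def test_msr_identical_scales_equal_weights_is_ssr(self, rng):
        ch = rng.uniform(0, 255, (12, 12))
        cfg = RetinexConfig(scales=(9.0, 9.0, 9.0))
        np.testing.assert_allclose(msr(ch, cfg), ssr(ch, 9.0), atol=1e-12)

    def test_msr_equal_weights_is_mean_of_ssr(self, rng):
        ch = rng.uniform(0, 255, (32, 32))
        cfg = RetinexConfig(scales=(5.0, 15.0, 40.0))
        expected = np.mean([ssr(ch, s) for s in cfg.scales], axis=0)
        np.testing.assert_allclose(msr(ch, cfg), expected, atol=1e-12)


class TestColorRestoration:
    def test_equal_channels_hand_value(self):
        img = np.full((2, 2, 3), 60.0)
        c = color_restoration(img, alpha=46.0, beta=125.0)
        np.testing.assert_allclose(c, 46.0 * np.log(125.0 / 3.0), rtol=1e-9)

    def test_unit_ratio_gives_zero(self):
        # beta * S_i / sum(S) = 1 for S = (1, 62, 62) with beta = 125
        img = np.array([[[1.0, 62.0, 62.0]]])
        c = color_restoration(img)
        assert c[0, 0, 0] == pytest.approx(0.0, abs=1e-4)

    def test_scale_invariance(self, rng):
        img = rng.uniform(5, 250, (6, 6, 3))
        np.testing.assert_allclose(color_restoration(img),
                                   color_restoration(2.0 * img), atol=1e-6)


class TestMsrcrAndPipeline:
    def test_output_is_valid_8bit(self, rng):
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        out = msrcr(img)
        assert out.dtype == np.uint8 and out.shape == img.shape

    def test_constant_image_gives_constant_output(self):
        img = np.full((24, 24, 3), 77, dtype=np.uint8)
        out = msrcr(img)
        for c in range(3):
            assert np.unique(out[..., c]).size == 1

    def test_compositional_oracle(self, rng):
        img = rng.uniform(0, 255, (32, 32, 3))
        cfg = RetinexConfig(scales=(3.0, 7.0, 15.0))
        refl = np.stack([msr(img[..., c], cfg) for c in range(3)], axis=2)
        expected = color_restoration(img, cfg.alpha, cfg.beta) * refl
        lo = np.percentile(expected, 1.0, axis=(0, 1))
        hi = np.percentile(expected, 99.0, axis=(0, 1))
        stretched = (np.clip(expected, lo, hi) - lo) / (hi - lo) * 255.0
        got = msrcr(img, cfg)
        assert np.abs(got.astype(float) - stretched).max() <= 0.5 + 1e-8

    def test_shape_preserved_and_deterministic(self, small_smear):
        img, _ = small_smear
        out1, out2 = ahe_retinex(img), ahe_retinex(img)
        assert out1.shape == img.shape
        np.testing.assert_array_equal(out1, out2)

    def test_contrast_strictly_increases_on_dark_fixture(self, dark_smear):
        img, mask = dark_smear
        out = ahe_retinex(img)

        def michelson(image):
            g = image.astype(float).mean(axis=2)
            f, b = g[mask > 0].mean(), g[mask == 0].mean()
            return abs(f - b) / (f + b)

        assert michelson(out) > michelson(img)
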