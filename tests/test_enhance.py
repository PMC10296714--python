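"""Enhancement-chain tests: rotations, filters vs brute-force oracles, the
HSI transform against hand-computed pixels, CLAHE/weight-map behavior, and
the composed pipeline contract."""

import numpy as np
import pytest

from endofeat import (EnhanceConfig, augment_rotations, apply_weight_map,
                      box_filter_3d, clahe_channel, enhance_pipeline,
                      ensemble_channels, median_filter_3d, rgb_to_hsi,
                      saturation_weight_map, unsharp_mask)
from endofeat.enhance import resize_image


def brute_box(plane, size):
    """Independent sliding-window mean with zero padding."""
    h = size // 2
    pad = np.pad(plane, h)
    out = np.empty_like(plane)
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            out[i, j] = pad[i:i + size, j:j + size].mean()
    return out


def brute_median(plane, size):
    h = size // 2
    pad = np.pad(plane, h)
    out = np.empty_like(plane)
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            out[i, j] = np.median(pad[i:i + size, j:j + size])
    return out


class TestRotations:
    def test_lossless_multiset_and_inverses(self, rng):
        img = rng.random((9, 13, 3))
        outs = augment_rotations(img)
        assert len(outs) == 4
        for k, out in enumerate(outs):
            assert np.array_equal(np.sort(out.ravel()), np.sort(img.ravel()))
            # undoing the right-rotation recovers the original exactly
            assert np.array_equal(np.rot90(out, k=k, axes=(0, 1)), img)

    def test_single_pixel_and_involution(self):
        px = np.full((1, 1, 3), 0.4)
        outs = augment_rotations(px)
        for out in outs:
            assert np.array_equal(out, px)
        img = np.random.default_rng(0).random((6, 6, 3))
        rot180 = augment_rotations(img)[2]
        assert np.array_equal(augment_rotations(rot180)[2], img)


class TestBoxFilter:
    @pytest.mark.parametrize("size", [3, 5])
    def test_matches_brute_force_oracle(self, rng, size):
        img = rng.random((16, 16, 3))
        out = box_filter_3d(img, size)
        for c in range(3):
            np.testing.assert_allclose(out[..., c], brute_box(img[..., c], size),
                                       atol=1e-9)

    def test_impulse_response(self):
        img = np.zeros((5, 5, 3))
        img[2, 2, :] = 1.0
        out = box_filter_3d(img, 3)
        expect = np.zeros((5, 5))
        expect[1:4, 1:4] = 1 / 9
        for c in range(3):
            np.testing.assert_allclose(out[..., c], expect, atol=1e-12)

    def test_constant_and_identity(self):
        img = np.full((8, 8, 3), 0.37)
        # interior of a constant image stays constant; size-1 is the identity
        np.testing.assert_allclose(box_filter_3d(img, 3)[1:-1, 1:-1], 0.37)
        np.testing.assert_allclose(box_filter_3d(img, 1), img)

    @pytest.mark.parametrize("size", [0, 2, -3])
    def test_rejects_bad_size(self, size):
        with pytest.raises(ValueError):
            box_filter_3d(np.zeros((4, 4, 3)), size)


class TestMedianFilter:
    def test_matches_brute_force_oracle(self, rng):
        img = rng.random((12, 12, 3))
        out = median_filter_3d(img, 3)
        for c in range(3):
            np.testing.assert_array_equal(out[..., c], brute_median(img[..., c], 3))

    def test_salt_removal_and_fixed_point(self):
        img = np.zeros((5, 5, 3))
        img[2, 3, :] = 1.0
        out = median_filter_3d(img, 3)
        assert np.all(out == 0)
        assert np.array_equal(median_filter_3d(out, 3), out)

    def test_rejects_even_size(self):
        with pytest.raises(ValueError):
            median_filter_3d(np.zeros((4, 4, 3)), 4)


class TestRgbToHsi:
    @pytest.mark.parametrize("rgb,hue,sat,inten", [
        ((1.0, 0.0, 0.0), 0.0, 1.0, 1 / 3),
        ((0.0, 0.0, 1.0), 240.0, 1.0, 1 / 3),
        ((0.5, 0.5, 0.5), 0.0, 0.0, 0.5),
        ((0.0, 1.0, 0.0), 120.0, 1.0, 1 / 3),
    ])
    def test_hand_computed_pixels(self, rgb, hue, sat, inten):
        img = np.array(rgb, dtype=float).reshape(1, 1, 3)
        hsi = rgb_to_hsi(img)
        assert hsi.hue[0, 0] == pytest.approx(hue, abs=1e-9)
        assert hsi.saturation[0, 0] == pytest.approx(sat, abs=1e-9)
        assert hsi.intensity[0, 0] == pytest.approx(inten, abs=1e-9)

    def test_random_pixel_invariants(self, rng):
        img = rng.random((20, 20, 3))
        hsi = rgb_to_hsi(img)
        lo = img.min(axis=-1)
        hi = img.max(axis=-1)
        assert np.all(hsi.intensity >= lo - 1e-12)
        assert np.all(hsi.intensity <= hi + 1e-12)
        assert np.all(hsi.hue >= 0) and np.all(hsi.hue < 360)
        assert np.all((hsi.saturation >= 0) & (hsi.saturation <= 1))
        # S vanishes iff the pixel is achromatic
        grey = np.abs(img - img.mean(axis=-1, keepdims=True)).max(axis=-1) < 1e-12
        assert np.array_equal(hsi.saturation < 1e-9, grey)

    def test_theta_reproduces_arccos_argument(self, rng):
        img = rng.random((15, 15, 3))
        r, g, b = img[..., 0], img[..., 1], img[..., 2]
        hsi = rgb_to_hsi(img)
        theta = np.where(b > g, 360.0 - hsi.hue, hsi.hue)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        ok = den > 1e-9
        np.testing.assert_allclose(np.cos(np.radians(theta))[ok],
                                   np.clip(num / den, -1, 1)[ok], atol=1e-9)


class TestClaheAndWeights:
    def test_constant_plane_unchanged(self):
        plane = np.full((32, 32), 0.6)
        np.testing.assert_array_equal(clahe_channel(plane), plane)

    def test_spreads_low_contrast_gradient(self):
        plane = np.tile(np.linspace(0.45, 0.55, 64), (64, 1))
        out = clahe_channel(plane)
        assert out.std() >= plane.std()
        assert out.min() >= 0 and out.max() <= 1

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            clahe_channel(np.zeros((8, 8)), clip=0)
        with pytest.raises(ValueError):
            clahe_channel(np.zeros((8, 8)), tiles=(0, 4))

    def test_weight_map_gaussian_shape(self):
        mu, sigma = 1.0, 0.3
        s = np.array([[mu, mu - sigma, 0.0]])
        w = saturation_weight_map(s, mu, sigma)
        assert w[0, 0] == pytest.approx(1.0)
        assert w[0, 1] == pytest.approx(np.exp(-0.5), abs=1e-12)
        # monotone non-increasing in |s - mu|
        grid = np.linspace(0, 1, 101)[None, :]
        wg = saturation_weight_map(grid, mu, sigma)
        assert np.all(np.diff(wg[0]) >= 0)  # mu=1: distance shrinks along grid
        with pytest.raises(ValueError):
            saturation_weight_map(s, 1.0, 0.0)

    def test_apply_weight_map_rescale(self, rng):
        plane = rng.random((10, 10))
        ones = np.ones_like(plane)
        base = apply_weight_map(plane, ones)
        np.testing.assert_allclose(
            base, (plane - plane.min()) / np.ptp(plane), atol=1e-12)
        # constant weights are equivalent to unit weights
        np.testing.assert_allclose(apply_weight_map(plane, 0.3 * ones), base,
                                   atol=1e-12)
        out = apply_weight_map(rng.random((6, 6)), rng.random((6, 6)))
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            apply_weight_map(plane, np.ones((3, 3)))


class TestEnsembleAndUnsharp:
    def test_ensemble_stacking_and_hue_rescale(self):
        a = np.full((4, 4), 180.0)
        b = np.full((4, 4), 0.25)
        c = np.full((4, 4), 0.75)
        out = ensemble_channels(a, b, c)
        np.testing.assert_allclose(out[..., 0], 0.5)
        np.testing.assert_array_equal(out[..., 1], b)
        np.testing.assert_array_equal(out[..., 2], c)
        with pytest.raises(ValueError):
            ensemble_channels(a, b, np.zeros((3, 3)))

    def test_unsharp_identity_cases(self, rng):
        img = rng.random((12, 12, 3))
        np.testing.assert_allclose(unsharp_mask(img, 1.0, 0.0), img)
        const = np.full((12, 12, 3), 0.4)
        np.testing.assert_allclose(unsharp_mask(const, 1.0, 2.0), const, atol=1e-12)

    def test_unsharp_overshoots_step_edge(self):
        img = np.zeros((16, 16, 3))
        img[:, 8:, :] = 0.6
        out = unsharp_mask(img, 1.0, 1.0)
        assert out.max() > img.max()


class TestPipeline:
    def test_contract_and_determinism(self, rng):
        img = rng.random((40, 30, 3))
        cfg = EnhanceConfig(working_size=(24, 24))
        r1 = enhance_pipeline(img, cfg)
        r2 = enhance_pipeline(img, cfg)
        assert r1.sharp_ensemble.shape == (24, 24, 3)
        assert r1.s_improved.shape == (24, 24)
        for arr in (r1.sharp_ensemble, r1.s_improved):
            assert arr.min() >= 0 and arr.max() <= 1
        assert np.array_equal(r1.sharp_ensemble, r2.sharp_ensemble)
        assert np.array_equal(r1.s_improved, r2.s_improved)

    def test_raises_lesion_contrast(self, lesion_batch):
        """Enhancement should increase lesion-vs-background intensity contrast
        on at least the batch average of lesion-bearing frames."""
        spec, images, labels, masks = lesion_batch
        cfg = EnhanceConfig(working_size=spec.size)
        gains = []
        for img, lbl, mask in zip(images, labels, masks):
            if lbl == "healthy" or not mask.any():
                continue
            raw_i = img.mean(axis=-1)  # intensity of the raw frame
            raw_contrast = abs(raw_i[mask].mean() - raw_i[~mask].mean())
            sharp, _ = enhance_pipeline(img, cfg)
            enh_i = sharp[..., 2]  # equalized intensity channel
            enh_contrast = abs(enh_i[mask].mean() - enh_i[~mask].mean())
            gains.append(enh_contrast - raw_contrast)
        assert np.mean(gains) > 0

    def test_resize_identity_when_at_size(self, rng):
        img = rng.random((16, 16, 3))
        assert np.array_equal(resize_image(img, (16, 16)), img)


def test_config_roundtrip_and_validation():
    cfg = EnhanceConfig(box_size=5, clahe_tiles=(4, 4))
    assert EnhanceConfig.from_dict(cfg.to_dict()) == cfg
    with pytest.raises(ValueError):
        EnhanceConfig(box_size=4)
    with pytest.raises(ValueError):
        EnhanceConfig(median_size=-1)
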