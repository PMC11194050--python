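"""Unit and property tests for the filter/morphology primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from facryst import imageops as io
from facryst.imageops import BinaryMask

import oracles


# ---------------------------------------------------------------------------
# rgb_to_hsb


def test_hsb_pure_red_is_hue_origin():
    img = np.full((2, 2, 3), (255, 0, 0), dtype=np.uint8)
    hsb = io.rgb_to_hsb(img)
    assert (hsb.hue == 0).all()
    assert (hsb.saturation == 255).all()
    assert (hsb.brightness == 255).all()


def test_hsb_achromatic_pixel():
    img = np.full((1, 1, 3), 128, dtype=np.uint8)
    hsb = io.rgb_to_hsb(img)
    assert hsb.saturation[0, 0] == 0
    assert hsb.brightness[0, 0] == 128


def test_hsb_yellow_maps_onto_8bit_axis():
    # 60 deg * 255/360 = 42.5 -> 43 under half-up rounding
    img = np.full((1, 1, 3), (255, 255, 0), dtype=np.uint8)
    assert io.rgb_to_hsb(img).hue[0, 0] == 43


def test_hsb_matches_closed_form_oracle(rng):
    img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
    hsb = io.rgb_to_hsb(img)
    for y in range(16):
        for x in range(16):
            h, s, v = oracles.hsb_oracle_pixel(*(int(c) for c in img[y, x]))
            assert hsb.brightness[y, x] == int(v)
            # implementation rounds in float32; allow the half-up boundary
            assert abs(float(hsb.hue[y, x]) - h) <= 0.5 + 1e-3
            assert abs(float(hsb.saturation[y, x]) - s) <= 0.5 + 1e-3


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(np.uint8, (7, 5, 3), elements=st.integers(0, 255)))
def test_hsb_brightness_is_channel_max(img):
    hsb = io.rgb_to_hsb(img)
    assert (hsb.brightness == img.max(axis=2)).all()


# ---------------------------------------------------------------------------
# threshold_band


def test_threshold_band_boundaries_inclusive():
    flat = np.full((4, 4), 25, dtype=np.uint8)
    assert (io.threshold_band(flat, 25, 50).pixels == 255).all()
    flat = np.full((4, 4), 0, dtype=np.uint8)
    assert (io.threshold_band(flat, 25, 50).pixels == 0).all()


def test_threshold_band_invalid_bounds():
    img = np.zeros((2, 2), dtype=np.uint8)
    with pytest.raises(ValueError):
        io.threshold_band(img, 50, 25)
    with pytest.raises(ValueError):
        io.threshold_band(img, -1, 10)


def test_threshold_band_matches_oracle(rng):
    img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    got = io.threshold_band(img, 25, 50).pixels
    np.testing.assert_array_equal(got, oracles.threshold_oracle(img, 25, 50))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(np.uint8, (6, 6), elements=st.integers(0, 255)))
def test_threshold_full_band_is_all_foreground(img):
    assert (io.threshold_band(img, 0, 255).pixels == 255).all()


# ---------------------------------------------------------------------------
# despeckle / remove_outliers


def test_despeckle_kills_isolated_pixel_and_keeps_constants():
    m = np.zeros((9, 9), dtype=np.uint8)
    m[4, 4] = 255
    assert (io.despeckle(m) == 0).all()
    const = np.full((9, 9), 77, dtype=np.uint8)
    np.testing.assert_array_equal(io.despeckle(const), const)


def test_despeckle_preserves_mask_type_and_scale():
    m = BinaryMask(np.zeros((5, 5), dtype=np.uint8), scale_factor=4)
    out = io.despeckle(m)
    assert isinstance(out, BinaryMask) and out.scale_factor == 4


def test_remove_outliers_vacuous_threshold(rng):
    img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
    np.testing.assert_array_equal(
        io.remove_outliers(img, radius=2, threshold=255, mode="bright"), img
    )


def test_remove_outliers_zaps_hot_pixel():
    img = np.zeros((11, 11), dtype=np.uint8)
    img[5, 5] = 255
    out = io.remove_outliers(img, radius=2, threshold=50, mode="bright")
    assert out[5, 5] == 0


def test_remove_outliers_matches_oracle(rng):
    for mode in ("bright", "dark"):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        got = io.remove_outliers(img, radius=2, threshold=50, mode=mode)
        exp = oracles.remove_outliers_oracle(img, 2, 50, mode)
        np.testing.assert_array_equal(got, exp)


# ---------------------------------------------------------------------------
# gaussian_blur / variance_filter


def test_gaussian_constant_unchanged():
    img = np.full((16, 16), 99, dtype=np.uint8)
    np.testing.assert_allclose(io.gaussian_blur(img, 2.0), 99.0, rtol=1e-12)


def test_gaussian_impulse_matches_kernel_values():
    # separable response: out(0, y) = k(0) * k(y) for the sampled, truncated,
    # normalized Gaussian kernel
    sigma = 1.5
    n = 33
    img = np.zeros((n, n), dtype=np.float64)
    img[n // 2, n // 2] = 1.0
    out = io.gaussian_blur(img, sigma)
    r = int(4 * sigma + 0.5)
    xs = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-0.5 * (xs / sigma) ** 2)
    k /= k.sum()
    row = out[n // 2, n // 2 - r : n // 2 + r + 1]
    np.testing.assert_allclose(row, k * k[r], rtol=1e-7, atol=1e-12)


def test_gaussian_conserves_interior_mass(rng):
    img = rng.uniform(0, 255, (64, 64))
    out = io.gaussian_blur(img, 2.0)
    # interior window far from the replicated border
    assert abs(out[16:48, 16:48].sum() / img[16:48, 16:48].sum() - 1) < 0.05


def test_variance_constant_is_zero():
    img = np.full((10, 10), 200, dtype=np.uint8)
    np.testing.assert_allclose(io.variance_filter(img, 2), 0.0, atol=1e-9)


def test_variance_peaks_on_step_boundary():
    img = np.zeros((12, 12), dtype=np.uint8)
    img[:, 6:] = 255
    var = io.variance_filter(img, 2)
    col_means = var.mean(axis=0)
    assert col_means.argmax() in (5, 6)


def test_variance_matches_oracle(rng):
    img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    got = io.variance_filter(img, 2)
    np.testing.assert_allclose(got, oracles.variance_oracle(img, 2), rtol=1e-9, atol=1e-7)


# ---------------------------------------------------------------------------
# dilate / fill_holes


def test_dilate_single_pixel_becomes_block():
    m = np.zeros((5, 5), dtype=np.uint8)
    m[2, 2] = 255
    out = io.dilate(BinaryMask(m), 1).pixels
    assert out[1:4, 1:4].min() == 255 and out.sum() == 255 * 9


def test_dilate_saturated_mask_unchanged():
    m = BinaryMask(np.full((6, 6), 255, dtype=np.uint8))
    np.testing.assert_array_equal(io.dilate(m, 3).pixels, m.pixels)


def test_dilate_matches_shift_union_oracle(rng):
    m = (rng.random((16, 16)) < 0.2).astype(np.uint8) * 255
    got = io.dilate(BinaryMask(m), 2).pixels
    np.testing.assert_array_equal(got, oracles.dilate_oracle(m, 2))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(bool, (10, 10)), hnp.arrays(bool, (10, 10)))
def test_dilate_is_monotone(a, b):
    small = a & b
    big = a | b
    d_small = io.dilate(BinaryMask(small.astype(np.uint8) * 255), 1).pixels
    d_big = io.dilate(BinaryMask(big.astype(np.uint8) * 255), 1).pixels
    assert ((d_small > 0) <= (d_big > 0)).all()


def test_fill_holes_ring_becomes_disc():
    m = np.zeros((9, 9), dtype=np.uint8)
    m[2:7, 2:7] = 255
    m[3:6, 3:6] = 0
    out = io.fill_holes(BinaryMask(m)).pixels
    assert (out[2:7, 2:7] == 255).all()


def test_fill_holes_matches_flood_fill_oracle(rng):
    m = (rng.random((16, 16)) < 0.45).astype(np.uint8) * 255
    got = io.fill_holes(BinaryMask(m)).pixels
    np.testing.assert_array_equal(got, oracles.fill_holes_oracle(m))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(bool, (12, 12)))
def test_fill_holes_is_idempotent(fg):
    m = BinaryMask(fg.astype(np.uint8) * 255)
    once = io.fill_holes(m)
    twice = io.fill_holes(once)
    np.testing.assert_array_equal(once.pixels, twice.pixels)


# ---------------------------------------------------------------------------
# rescaling


def test_downscale_constant():
    img = np.full((8, 8), 31, dtype=np.uint8)
    out = io.downscale_average(img, 4)
    assert out.shape == (2, 2) and (out == 31).all()


def test_downscale_rounds_half_up():
    img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
    assert io.downscale_average(img, 2)[0, 0] == 128  # mean 127.5 -> 128


def test_downscale_crops_trailing_remainder():
    img = np.arange(9 * 7, dtype=np.uint8).reshape(9, 7)
    out = io.downscale_average(img, 4)
    assert out.shape == (2, 1)


def test_downscale_mean_of_means_on_block_constant(rng):
    base = rng.integers(0, 256, (4, 4), dtype=np.uint8)
    img = np.repeat(np.repeat(base, 4, axis=0), 4, axis=1)
    once = io.downscale_average(img, 4)
    twice = io.downscale_average(io.downscale_average(img, 2), 2)
    np.testing.assert_array_equal(once, twice)
    np.testing.assert_array_equal(once, base)


def test_upscale_mask_replicates_blocks():
    m = np.zeros((3, 3), dtype=np.uint8)
    m[1, 1] = 255
    out = io.upscale_mask(BinaryMask(m, scale_factor=4), 4)
    assert out.pixels.shape == (12, 12)
    assert out.pixels.sum() == 255 * 16
    assert out.scale_factor == 1


def test_upscale_downscale_roundtrip_on_block_constant(rng):
    base = (rng.random((6, 6)) < 0.5).astype(np.uint8) * 255
    m = BinaryMask(np.repeat(np.repeat(base, 4, axis=0), 4, axis=1), 1)
    down = io.downscale_average(m.pixels, 4)
    up = io.upscale_mask(BinaryMask(down, 4), 4)
    np.testing.assert_array_equal(up.pixels, m.pixels)


# ---------------------------------------------------------------------------
# raw integrated density


def test_rid_zero_image():
    z = np.zeros((8, 8), dtype=np.uint8)
    assert io.raw_integrated_density(z, np.full((8, 8), 255, dtype=np.uint8)) == 0.0


def test_rid_binary_counts():
    img = np.zeros((8, 8), dtype=np.uint8)
    img[2:5, 2:5] = 255
    roi = np.full((8, 8), 255, dtype=np.uint8)
    assert io.raw_integrated_density(img, roi) == 255.0 * 9


def test_rid_matches_masked_loop(rng):
    img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    roi = (rng.random((16, 16)) < 0.5).astype(np.uint8) * 255
    assert io.raw_integrated_density(img, roi) == oracles.rid_oracle(img, roi)


def test_rid_resolution_mismatch_raises():
    with pytest.raises(io.ScaleMismatchError):
        io.raw_integrated_density(
            np.zeros((8, 8), dtype=np.uint8), np.zeros((4, 4), dtype=np.uint8)
        )


# ---------------------------------------------------------------------------
# rotation commutation


@pytest.mark.parametrize(
    "op",
    [
        lambda a: io.despeckle(a),
        lambda a: io.remove_outliers(a, 2, 50, "bright"),
        lambda a: io.threshold_band(a, 25, 50).pixels,
        lambda a: io.dilate(BinaryMask((a > 128).astype(np.uint8) * 255), 1).pixels,
        lambda a: io.fill_holes(BinaryMask((a > 128).astype(np.uint8) * 255)).pixels,
    ],
    ids=["despeckle", "remove_outliers", "threshold", "dilate", "fill_holes"],
)
def test_integer_ops_commute_with_rot90(rng, op):
    img = rng.integers(0, 256, (24, 24), dtype=np.uint8)
    np.testing.assert_array_equal(op(np.rot90(img).copy()), np.rot90(op(img)))


def test_variance_commutes_with_rot90(rng):
    img = rng.integers(0, 256, (24, 24), dtype=np.uint8)
    np.testing.assert_allclose(
        io.variance_filter(np.rot90(img).copy(), 2),
        np.rot90(io.variance_filter(img, 2)),
        rtol=1e-12,
        atol=1e-9,
    )
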