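"""Pixel-feature extraction: HSV conversion, hue classification, and
the 17 per-photo statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naive_oracles import naive_pixel_features

from phototraits import (
    COLOR_NAMES,
    HUE_BOUNDARIES,
    PhotoPixelFeatures,
    average_pixel_features,
    classify_hue,
    extract_pixel_features,
    extract_pixel_features_batch,
    load_image,
    rgb_to_hsv,
)


@pytest.mark.parametrize(
    "pixel, expected",
    [
        ((255, 0, 0), (0.0, 255.0, 255.0)),     # pure red
        ((128, 128, 128), (0.0, 0.0, 128.0)),   # achromatic
        ((0, 255, 0), (60.0, 255.0, 255.0)),    # green: 120° -> 60 half-deg
        ((0, 0, 0), (0.0, 0.0, 0.0)),           # black
    ],
)
def test_rgb_to_hsv_examples(pixel, expected):
    assert rgb_to_hsv(pixel) == pytest.approx(expected)


def test_rgb_to_hsv_rejects_out_of_range():
    with pytest.raises(ValueError):
        rgb_to_hsv((256, 0, 0))
    with pytest.raises(ValueError):
        rgb_to_hsv((-1, 10, 10))


@given(st.tuples(*[st.integers(0, 255)] * 3))
@settings(max_examples=200, deadline=None)
def test_rgb_to_hsv_matches_skimage(pixel):
    """The hexcone conversion agrees with the scikit-image reference."""
    from skimage.color import rgb2hsv

    h, s, v = rgb_to_hsv(pixel)
    ref = rgb2hsv(np.array([[pixel]], dtype=np.uint8))[0, 0]
    assert v == pytest.approx(ref[2] * 255.0, abs=1e-6)
    assert s == pytest.approx(ref[1] * 255.0, abs=1e-6)
    # hue comparison modulo the circle
    diff = abs(h - ref[0] * 180.0) % 180.0
    assert min(diff, 180.0 - diff) == pytest.approx(0.0, abs=1e-3)


@pytest.mark.parametrize(
    "h, color",
    [(0, "red"), (6.99, "red"), (7, "orange"), (15, "orange"),
     (23, "yellow"), (34.5, "yellow"), (35, "green"), (89.9, "green"),
     (90, "blue"), (129, "blue"), (130, "violet"), (168.9, "violet"),
     (169, "red"), (172, "red"), (179.5, "red")],
)
def test_classify_hue_examples(h, color):
    assert classify_hue(h) == color


def test_hue_intervals_tile_the_circle():
    """Every integer hue 0..179 maps to exactly one color and interval
    widths sum to the full 180 half-degrees."""
    counts = dict.fromkeys(COLOR_NAMES, 0)
    for h in range(180):
        counts[classify_hue(h)] += 1
    assert sum(counts.values()) == 180
    widths = np.diff((0,) + HUE_BOUNDARIES)
    assert widths.sum() + (180 - HUE_BOUNDARIES[-1]) == 180
    # red's wrap-around width: [169,180) plus [0,7)
    assert counts["red"] == (180 - 169) + 7


def test_classify_hue_out_of_range():
    for h in (-0.1, 180.0, 250):
        with pytest.raises(ValueError):
            classify_hue(h)


def test_uniform_image_features():
    img = np.full((8, 12, 3), (200, 50, 50), dtype=np.uint8)
    f = extract_pixel_features(img)
    assert (f.r_mean, f.g_mean, f.b_mean) == (200.0, 50.0, 50.0)
    assert (f.r_var, f.g_var, f.b_var) == (0.0, 0.0, 0.0)
    assert f.warm_share == 1.0  # hue 0 -> red
    assert f.red_share == 1.0


def test_constructed_color_composition():
    """70% blue-hue pixels and 30% orange-hue pixels give exactly those
    shares, and warm share counts only the orange."""
    # h=100 (blue): hue 200°, e.g. RGB (0, 85, 255); h=10 (orange): 20°
    blue = np.array([0, 85, 255], dtype=np.uint8)
    orange = np.array([255, 85, 0], dtype=np.uint8)
    img = np.empty((10, 10, 3), dtype=np.uint8)
    img.reshape(-1, 3)[:70] = blue
    img.reshape(-1, 3)[70:] = orange
    f = extract_pixel_features(img)
    assert f.blue_share == 0.7
    assert f.orange_share == 0.3
    assert f.warm_share == 0.3


def test_checkerboard_value_variance():
    """Equal-count black/white field: two-point distribution closed form
    gives val_mean 127.5 and val_var (255/2)^2 = 16256.25."""
    img = np.zeros((8, 8, 3), dtype=np.uint8)
    img[::2, ::2] = 255
    img[1::2, 1::2] = 255
    f = extract_pixel_features(img)
    assert f.val_mean == 127.5
    assert f.val_var == 16256.25


def test_extraction_matches_naive_oracle(rng):
    """Vectorised features equal a per-pixel double-loop oracle."""
    for _ in range(5):
        img = rng.integers(0, 256, size=(9, 7, 3), dtype=np.uint8)
        got = extract_pixel_features(img).as_array()
        want = naive_pixel_features(img)
        np.testing.assert_allclose(got, want, atol=1e-9, rtol=0)


def test_shares_sum_to_one_and_permutation_invariance(rng):
    img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    f = extract_pixel_features(img)
    shares = [f.orange_share, f.yellow_share, f.green_share,
              f.blue_share, f.violet_share, f.red_share]
    assert sum(shares) == pytest.approx(1.0, abs=1e-9)
    flat = img.reshape(-1, 3)
    perm = flat[rng.permutation(len(flat))].reshape(img.shape)
    np.testing.assert_allclose(extract_pixel_features(perm).as_array(),
                               f.as_array(), atol=1e-12)


def test_batch_equals_single(rng):
    stack = rng.integers(0, 256, size=(40, 12, 12, 3), dtype=np.uint8)
    batch = extract_pixel_features_batch(stack)
    for i in range(stack.shape[0]):
        np.testing.assert_allclose(
            batch[i], extract_pixel_features(stack[i]).as_array(),
            atol=1e-9, rtol=0)


def test_average_pixel_features(rng):
    f = extract_pixel_features(rng.integers(0, 256, (6, 6, 3), dtype=np.uint8))
    np.testing.assert_allclose(  # idempotent mean
        average_pixel_features([f] * 5).as_array(), f.as_array(),
        rtol=1e-15, atol=0)
    a = PhotoPixelFeatures.from_array(rng.random(17))
    b = PhotoPixelFeatures.from_array(rng.random(17))
    avg = average_pixel_features([a, b])
    np.testing.assert_allclose(avg.as_array(), (a.as_array() + b.as_array()) / 2)
    # brute-force field-wise loop oracle over many random fixtures
    import dataclasses

    feats = [PhotoPixelFeatures.from_array(rng.random(17)) for _ in range(100)]
    got = average_pixel_features(feats).as_array()
    want = np.array([
        sum(getattr(p, fld.name) for p in feats) / len(feats)
        for fld in dataclasses.fields(PhotoPixelFeatures)
    ])
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_degenerate_inputs():
    with pytest.raises(ValueError):
        extract_pixel_features(np.empty((0, 3, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        average_pixel_features([])
    with pytest.raises(ValueError):
        extract_pixel_features(np.full((2, 2, 3), 300.0))


def test_load_image_normalises_modes(tmp_path):
    from PIL import Image

    rgba = np.zeros((4, 4, 4), dtype=np.uint8)
    rgba[..., 0] = 200
    rgba[..., 3] = 255
    Image.fromarray(rgba, "RGBA").save(tmp_path / "a.png")
    arr = load_image(tmp_path / "a.png")
    assert arr.shape == (4, 4, 3)
    assert arr[..., 0].max() == 200

    gray = np.full((5, 5), 77, dtype=np.uint8)
    Image.fromarray(gray, "L").save(tmp_path / "g.png")
    arr = load_image(tmp_path / "g.png")
    assert arr.shape == (5, 5, 3)
    assert (arr == 77).all()
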