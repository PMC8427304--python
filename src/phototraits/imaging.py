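"""Low-level (pixel) photograph features.

Every photograph is reduced to 17 numbers: per-channel RGB mean and
population variance (6), saturation and value (brightness) mean and
variance (4), the share of pixels falling in each of six hue intervals
(orange, yellow, green, blue, violet, red), and the share of pixels with
warm colors (red + orange + yellow).

Hue follows the half-degree convention common in 8-bit image pipelines:
the hue circle [0, 360) degrees is stored as [0, 180).  The six color
intervals are bounded at [7, 23, 35, 90, 130, 169]; red wraps around zero
(h < 7 or h >= 169).  Achromatic pixels (R = G = B) carry the h = 0
convention and therefore count as red.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "COLOR_NAMES",
    "WARM_COLORS",
    "HUE_BOUNDARIES",
    "PhotoPixelFeatures",
    "rgb_to_hsv",
    "classify_hue",
    "extract_pixel_features",
    "extract_pixel_features_batch",
    "average_pixel_features",
    "load_image",
]

#: The six hue classes in boundary order; index i covers hues in
#: [HUE_BOUNDARIES[i-1], HUE_BOUNDARIES[i]) with red wrapping across 0.
COLOR_NAMES = ("orange", "yellow", "green", "blue", "violet", "red")
WARM_COLORS = frozenset({"red", "orange", "yellow"})
HUE_BOUNDARIES = (7.0, 23.0, 35.0, 90.0, 130.0, 169.0)

# digitize bin index -> color name (below 7 and above 169 are both red)
_BIN_TO_COLOR = ("red", "orange", "yellow", "green", "blue", "violet", "red")

#: Column order used throughout the package for the 17 pixel features.
PIXEL_FEATURE_COLUMNS = (
    "r_mean", "g_mean", "b_mean",
    "r_var", "g_var", "b_var",
    "sat_mean", "sat_var",
    "val_mean", "val_var",
    "orange_share", "yellow_share", "green_share",
    "blue_share", "violet_share", "red_share",
    "warm_share",
)


@dataclass(frozen=True)
class PhotoPixelFeatures:
    """The 17 low-level features of one photograph (or a user average)."""

    r_mean: float
    g_mean: float
    b_mean: float
    r_var: float
    g_var: float
    b_var: float
    sat_mean: float
    sat_var: float
    val_mean: float
    val_var: float
    orange_share: float
    yellow_share: float
    green_share: float
    blue_share: float
    violet_share: float
    red_share: float
    warm_share: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "PhotoPixelFeatures":
        a = np.asarray(a, dtype=float)
        if a.shape != (17,):
            raise ValueError("expected 17 feature values")
        return cls(*a.tolist())

    @property
    def color_share(self) -> dict:
        return {c: getattr(self, f"{c}_share") for c in COLOR_NAMES}


def _validate_channels(arr: np.ndarray) -> None:
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")


def rgb_to_hsv(pixel: Sequence[float]) -> tuple[float, float, float]:
    """Convert one RGB pixel (0–255 per channel) to (h, s, v).

    Uses the hexcone model: V = max(R,G,B); S = 0 if V = 0 else
    255·(V−min)/V; hue from the max-channel piecewise rule, returned in
    half-degrees in [0, 180).  Achromatic pixels return h = 0, s = 0.
    """
    r, g, b = (float(x) for x in pixel)
    arr = np.array([r, g, b])
    _validate_channels(arr)
    v = arr.max()
    mn = arr.min()
    delta = v - mn
    s = 0.0 if v == 0 else 255.0 * delta / v
    if delta == 0:
        h_deg = 0.0
    elif v == r:
        h_deg = 60.0 * ((g - b) / delta) % 360.0
    elif v == g:
        h_deg = 60.0 * ((b - r) / delta) + 120.0
    else:
        h_deg = 60.0 * ((r - g) / delta) + 240.0
    return h_deg / 2.0, s, v


def classify_hue(h: float) -> str:
    """Map a half-degree hue in [0, 180) to one of the six color names."""
    h = float(h)
    if not (0.0 <= h < 180.0):
        raise ValueError(f"hue {h} outside [0, 180)")
    idx = int(np.digitize(h, HUE_BOUNDARIES))
    return _BIN_TO_COLOR[idx]


def _mean_var(arr: np.ndarray, sq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population mean/variance over axis 1 via exact float64 moment sums."""
    m1 = arr.mean(axis=1, dtype=np.float64)
    var = sq.mean(axis=1, dtype=np.float64) - m1 * m1
    return m1, np.maximum(var, 0.0)


def _feature_block(arr: np.ndarray) -> np.ndarray:
    """The 17 features for a flattened batch (m, n_pixels, 3) -> (m, 17).

    Works on uint8 (fast, exact integer moments) or float64 pixels.
    Hue is computed in float32 for speed; its only use is interval
    classification, and boundary-exact hues are integer ratios that
    float32 division reproduces exactly, so the classification matches
    the float64 scalar path bit for bit.
    """
    m, n, _ = arr.shape
    chans = [np.ascontiguousarray(arr[..., i]) for i in range(3)]
    if arr.dtype == np.uint8:
        rf, gf, bf = (c.astype(np.float32) for c in chans)
    else:
        rf, gf, bf = (np.asarray(c, np.float32) for c in chans)
    v32 = np.maximum(np.maximum(rf, gf), bf)
    mn32 = np.minimum(np.minimum(rf, gf), bf)

    if arr.dtype == np.uint8:
        # exact integer moment sums (fits int64 comfortably)
        m1 = [c.sum(axis=1, dtype=np.int64) / n for c in chans]
        m2 = [(c.astype(np.uint16) ** 2).sum(axis=1, dtype=np.int64) / n
              for c in chans]
        rgb_mean = np.stack(m1, 1)
        rgb_var = np.maximum(np.stack(m2, 1) - rgb_mean * rgb_mean, 0.0)
    else:
        rgb_mean = np.stack([c.mean(axis=1, dtype=np.float64) for c in chans], 1)
        rgb_var = np.stack([_mean_var(c, c * c)[1] for c in chans], 1)

    d64 = (v32 - mn32).astype(np.float64)
    s = 255.0 * d64 / np.maximum(v32, 1.0)  # delta=0 when v=0, so s=0 there
    sat_mean, sat_var = _mean_var(s, s * s)
    vf = v32.astype(np.float64)
    val_mean, val_var = _mean_var(vf, vf * vf)

    # hue -> color-interval bins (0..6; 0 and 6 are red's wrap-around).
    # delta=0 makes every numerator 0, so achromatic pixels land at h=0.
    safe = np.maximum(v32 - mn32, np.float32(1))
    h_r = np.float32(60) * (gf - bf) / safe
    h_r = np.where(h_r < 0, h_r + np.float32(360), h_r)  # cheap mod 360
    h = np.where(
        v32 == rf, h_r,
        np.where(v32 == gf, np.float32(60) * (bf - rf) / safe + np.float32(120),
                 np.float32(60) * (rf - gf) / safe + np.float32(240)),
    ) * np.float32(0.5)
    h = np.where(h >= 180.0, h - np.float32(180), h)
    bins = np.zeros(h.shape, dtype=np.uint8)
    for bound in HUE_BOUNDARIES:
        bins += h >= bound
    flat = bins.astype(np.int32) + (np.arange(m, dtype=np.int32) * 7)[:, None]
    counts = np.bincount(flat.ravel(), minlength=7 * m).reshape(m, 7)
    # sum counts before dividing so each share is a single rounding
    red = (counts[:, 0] + counts[:, 6]) / n
    orange = counts[:, 1] / n
    yellow = counts[:, 2] / n
    green, blue, violet = counts[:, 3] / n, counts[:, 4] / n, counts[:, 5] / n
    warm = (counts[:, 0] + counts[:, 1] + counts[:, 2] + counts[:, 6]) / n

    return np.column_stack([
        rgb_mean[:, 0], rgb_mean[:, 1], rgb_mean[:, 2],
        rgb_var[:, 0], rgb_var[:, 1], rgb_var[:, 2],
        sat_mean, sat_var, val_mean, val_var,
        orange, yellow, green, blue, violet, red, warm,
    ])


def extract_pixel_features(image: np.ndarray) -> PhotoPixelFeatures:
    """Extract the 17 pixel features from one H×W×3 RGB image (0–255).

    Means and variances are population statistics over all pixels;
    color shares always sum to 1.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:  # grayscale: promote to R=G=B
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("image must be an H×W×3 RGB array")
    if arr.shape[0] * arr.shape[1] == 0:
        raise ValueError("image has no pixels")
    _validate_channels(arr)
    flat = arr.reshape(1, -1, 3)
    return PhotoPixelFeatures.from_array(_feature_block(flat)[0])


try:  # fused single-pass kernel for uint8 stacks
    import numba as _nb

    @_nb.njit(cache=True)
    def _feature_block_u8(flat):  # pragma: no cover - exercised via wrapper
        m, n, _ = flat.shape
        bounds = np.array([7.0, 23.0, 35.0, 90.0, 130.0, 169.0])
        out = np.empty((m, 17))
        for i in range(m):
            s_rgb = np.zeros(3)
            s_rgb2 = np.zeros(3)
            s_s = 0.0
            s_s2 = 0.0
            s_v = 0.0
            s_v2 = 0.0
            counts = np.zeros(7)
            for j in range(n):
                r = np.float64(flat[i, j, 0])
                g = np.float64(flat[i, j, 1])
                b = np.float64(flat[i, j, 2])
                s_rgb[0] += r
                s_rgb[1] += g
                s_rgb[2] += b
                s_rgb2[0] += r * r
                s_rgb2[1] += g * g
                s_rgb2[2] += b * b
                v = max(r, g, b)
                mn = min(r, g, b)
                delta = v - mn
                s = 0.0 if v == 0.0 else 255.0 * delta / v
                s_s += s
                s_s2 += s * s
                s_v += v
                s_v2 += v * v
                if delta == 0.0:
                    h = 0.0
                elif v == r:
                    h = (60.0 * (g - b) / delta) % 360.0
                elif v == g:
                    h = 60.0 * (b - r) / delta + 120.0
                else:
                    h = 60.0 * (r - g) / delta + 240.0
                h *= 0.5
                if h >= 180.0:
                    h -= 180.0
                k = 0
                for bnd in bounds:
                    if h >= bnd:
                        k += 1
                counts[k] += 1.0
            inv = 1.0 / n
            for c in range(3):
                out[i, c] = s_rgb[c] * inv
                out[i, 3 + c] = max(s_rgb2[c] * inv - out[i, c] * out[i, c], 0.0)
            out[i, 6] = s_s * inv
            out[i, 7] = max(s_s2 * inv - out[i, 6] * out[i, 6], 0.0)
            out[i, 8] = s_v * inv
            out[i, 9] = max(s_v2 * inv - out[i, 8] * out[i, 8], 0.0)
            out[i, 10] = counts[1] / n     # orange
            out[i, 11] = counts[2] / n     # yellow
            out[i, 12] = counts[3] / n     # green
            out[i, 13] = counts[4] / n     # blue
            out[i, 14] = counts[5] / n     # violet
            out[i, 15] = (counts[0] + counts[6]) / n  # red (wraps)
            out[i, 16] = (counts[0] + counts[1] + counts[2] + counts[6]) / n
        return out

except ImportError:  # pragma: no cover
    _feature_block_u8 = None


def extract_pixel_features_batch(stack: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Extract pixel features for a stack of images (N, H, W, 3) -> (N, 17).

    Processes in chunks to bound the float64 working set; identical in
    result to calling :func:`extract_pixel_features` per image.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[-1] != 3:
        raise ValueError("stack must be (N, H, W, 3)")
    if stack.dtype == np.uint8 and _feature_block_u8 is not None:
        return _feature_block_u8(
            np.ascontiguousarray(stack).reshape(stack.shape[0], -1, 3)
        )
    out = np.empty((stack.shape[0], 17), dtype=float)
    for start in range(0, stack.shape[0], chunk):
        part = stack[start:start + chunk]
        if part.dtype != np.uint8:
            part = part.astype(np.float64)
            _validate_channels(part)
        out[start:start + part.shape[0]] = _feature_block(
            part.reshape(part.shape[0], -1, 3)
        )
    return out


def average_pixel_features(
    per_photo: Iterable[PhotoPixelFeatures | Sequence[float]],
) -> PhotoPixelFeatures:
    """Unweighted mean of every feature across photos.

    Photos weigh equally regardless of pixel count — the per-user
    aggregation rule for low-level features.
    """
    rows = [
        p.as_array() if isinstance(p, PhotoPixelFeatures) else np.asarray(p, float)
        for p in per_photo
    ]
    if not rows:
        raise ValueError("need at least one photo")
    return PhotoPixelFeatures.from_array(np.mean(rows, axis=0))


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an 8-bit RGB array (alpha dropped, palettes
    expanded, grayscale promoted)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
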