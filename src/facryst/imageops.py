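"""Color-space conversion and neighborhood-filter primitives.

These are the building blocks the slide pipeline composes: an 8-bit
hue/saturation/brightness decomposition, band thresholding, the classic
denoising trio (3x3 median "despeckle", conditional-median outlier removal,
local variance), binary morphology (dilation, hole filling), block
down/upscaling and masked integrated density.

All primitives use deterministic conventions so they can be pinned against
brute-force per-pixel oracles:

* neighborhood filters replicate edge pixels at the border,
* 8-bit outputs round half up,
* disc neighborhoods contain offsets with dx**2 + dy**2 <= radius**2,
* median of an even-sized window is the upper-middle order statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class PipelineError(Exception):
    """Base class for pipeline failures."""


class ScaleMismatchError(PipelineError):
    """Two images that must share a resolution do not."""


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties toward +inf; preserves float dtype."""
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float64)
    return np.floor(a + a.dtype.type(0.5))


def _as_u8(x: np.ndarray) -> np.ndarray:
    return np.clip(round_half_up(x), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# containers


@dataclass
class HSBImage:
    """8-bit hue/saturation/brightness decomposition of an RGB image.

    Hue maps the [0, 360) color angle onto 0-255 (yellow ~60 deg -> ~43);
    saturation and brightness are on 0-255. Brightness equals the per-pixel
    channel maximum exactly.
    """

    hue: np.ndarray
    saturation: np.ndarray
    brightness: np.ndarray


@dataclass
class BinaryMask:
    """H x W segmentation mask over {0, 255}.

    ``scale_factor`` ties the mask to the full-resolution slide: 1 means
    native resolution, 4 means each mask pixel covers a 4x4 block of the
    original image.
    """

    pixels: np.ndarray
    scale_factor: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.pixels))

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.pixels.copy(), self.scale_factor)


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check an H x W x 3 uint8 image contract and return the array."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise ValueError(f"expected 8-bit RGB image, got dtype {img.dtype}")
    return img


# ---------------------------------------------------------------------------
# color space


def rgb_to_hsb(img: np.ndarray) -> HSBImage:
    """Decompose an 8-bit RGB image into 8-bit hue/saturation/brightness.

    Standard hexcone model: brightness = max(R, G, B);
    saturation = 255 * (max - min) / max (0 where max = 0); hue is the
    usual piecewise angle in degrees mapped onto the 0-255 scale with
    half-up rounding. Achromatic pixels get hue 0 and saturation 0.
    """
    img = validate_rgb(img)
    r = img[..., 0].astype(np.float32)
    g = img[..., 1].astype(np.float32)
    b = img[..., 2].astype(np.float32)

    v = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = v - mn

    sat = 255.0 * delta / np.maximum(v, np.float32(1.0))

    safe = np.maximum(delta, np.float32(1.0))
    hue6 = np.where(
        v == r,
        np.mod((g - b) / safe, np.float32(6.0)),
        np.where(v == g, (b - r) / safe + 2.0, (r - g) / safe + 4.0),
    )
    hue6[delta == 0] = 0.0
    hue = _as_u8(hue6 * np.float32(60.0 * 255.0 / 360.0))
    return HSBImage(hue=hue, saturation=_as_u8(sat), brightness=v.astype(np.uint8))


def hsb_to_rgb(hue: float, saturation: float, brightness: float) -> tuple[int, int, int]:
    """Inverse hexcone conversion for a single 8-bit HSB triple.

    Used by the synthetic renderer to paint features by their hue.
    """
    h = (float(hue) / 255.0) * 360.0
    s = float(saturation) / 255.0
    v = float(brightness)
    c = v * s
    hp = (h / 60.0) % 6.0
    x = c * (1.0 - abs(hp % 2.0 - 1.0))
    sector = int(hp)
    rgb1 = [(c, x, 0.0), (x, c, 0.0), (0.0, c, x), (0.0, x, c), (x, 0.0, c), (c, 0.0, x)][
        sector % 6
    ]
    m = v - c
    return tuple(int(np.clip(np.floor(ch + m + 0.5), 0, 255)) for ch in rgb1)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# thresholding


def threshold_band(
    channel: np.ndarray, lo: int, hi: int, scale_factor: int = 1
) -> BinaryMask:
    """Band-pass threshold: 255 where lo <= value <= hi (inclusive), else 0."""
    if not (0 <= lo <= hi <= 255):
        raise ValueError(f"invalid band [{lo}, {hi}]: need 0 <= lo <= hi <= 255")
    channel = np.asarray(channel)
    mask = ((channel >= lo) & (channel <= hi)).astype(np.uint8) * 255
    return BinaryMask(mask, scale_factor=scale_factor)


# ---------------------------------------------------------------------------
# neighborhood filters


def _disc_footprint(radius: float) -> np.ndarray:
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= radius * radius


def despeckle(img):
    """3x3 median filter (the classic 'despeckle'), edge-replicated.

    Accepts a grayscale array or a BinaryMask and returns the same type.
    """
    if isinstance(img, BinaryMask):
        out = ndimage.median_filter(img.pixels, size=3, mode="nearest")
        return BinaryMask(out, img.scale_factor)
    return ndimage.median_filter(np.asarray(img), size=3, mode="nearest")


def remove_outliers(
    img: np.ndarray,
    radius: float = 2.0,
    threshold: float = 50.0,
    mode: str = "bright",
) -> np.ndarray:
    """Conditional median replacement of outlier pixels.

    A pixel is replaced by the median of its disc neighborhood iff it
    deviates from that median by more than ``threshold`` in the chosen
    direction: ``bright`` removes pixels far above the median, ``dark``
    pixels far below it. Everything else is left untouched.
    """
    if mode not in ("bright", "dark"):
        raise ValueError(f"mode must be 'bright' or 'dark', got {mode!r}")
    arr = np.asarray(img)
    med = ndimage.median_filter(arr, footprint=_disc_footprint(radius), mode="nearest")
    a = arr.astype(np.float64)
    m = med.astype(np.float64)
    deviates = (a - m > threshold) if mode == "bright" else (m - a > threshold)
    return np.where(deviates, med, arr)


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian convolution with edge replication; returns float64."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return ndimage.gaussian_filter(
        np.asarray(img, dtype=np.float64), sigma=sigma, mode="nearest"
    )


def variance_filter(img: np.ndarray, radius: float) -> np.ndarray:
    """Local variance over a disc neighborhood; continuous (float64) output."""
    fp = _disc_footprint(radius).astype(np.float64)
    n = fp.sum()
    a = np.asarray(img, dtype=np.float64)
    s1 = ndimage.correlate(a, fp, mode="nearest")
    s2 = ndimage.correlate(a * a, fp, mode="nearest")
    var = s2 / n - (s1 / n) ** 2
    return np.maximum(var, 0.0)


# ---------------------------------------------------------------------------
# binary morphology


_STRUCT8 = np.ones((3, 3), dtype=bool)


def dilate(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Iterated 8-connected (3x3) binary dilation."""
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    fg = ndimage.binary_dilation(
        mask.pixels > 0, structure=_STRUCT8, iterations=iterations
    )
    return BinaryMask(fg.astype(np.uint8) * 255, mask.scale_factor)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background components not 4-connected to the image border."""
    fg = ndimage.binary_fill_holes(mask.pixels > 0)
    return BinaryMask(fg.astype(np.uint8) * 255, mask.scale_factor)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 8-connected foreground component.

    Stands in for an interactive wand click on the dominant object; ties
    break on the first label in raster order.
    """
    labels, n = ndimage.label(mask.pixels > 0, structure=_STRUCT8)
    if n == 0:
        return BinaryMask(np.zeros_like(mask.pixels), mask.scale_factor)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    return BinaryMask((labels == keep).astype(np.uint8) * 255, mask.scale_factor)


# ---------------------------------------------------------------------------
# rescaling


def downscale_average(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-average downscale by an integer factor.

    Each output pixel is the mean of its factor x factor source block
    (rounded half up for 8-bit inputs). Trailing rows/columns that do not
    fill a block are cropped.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    arr = np.asarray(img)
    h, w = arr.shape[0] - arr.shape[0] % factor, arr.shape[1] - arr.shape[1] % factor
    arr = arr[:h, :w]
    if arr.ndim == 3:
        blocks = arr.reshape(h // factor, factor, w // factor, factor, arr.shape[2])
    else:
        blocks = arr.reshape(h // factor, factor, w // factor, factor)
    mean = blocks.mean(axis=(1, 3), dtype=np.float64)
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        return _as_u8(mean)
    return mean


def upscale_mask(mask: BinaryMask, factor: int) -> BinaryMask:
    """Nearest-neighbor upscale: each pixel becomes a factor x factor block."""
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    up = np.repeat(np.repeat(mask.pixels, factor, axis=0), factor, axis=1)
    new_scale = mask.scale_factor // factor if mask.scale_factor % factor == 0 else 1
    return BinaryMask(up, max(new_scale, 1))


# ---------------------------------------------------------------------------
# measurement


def raw_integrated_density(img: np.ndarray, roi: np.ndarray) -> float:
    """Sum of pixel values over the ROI foreground.

    For 0/255 binary images this is 255 x the foreground pixel count inside
    the ROI. Both arrays must be at the same resolution.
    """
    img = np.asarray(img)
    roi = np.asarray(roi)
    if img.shape != roi.shape:
        raise ScaleMismatchError(
            f"image {img.shape} and ROI {roi.shape} are at different resolutions"
        )
    return float(img[roi > 0].sum(dtype=np.float64))
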