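"""Stage 1: delineate the whole renal slice and compute its centroid.

The goal is only a circumscribing selection, so the processing can be
aggressive: work at 1/4 scale, isolate tissue from the bright background by
thresholding the saturation map, clean the mask with dilation / despeckle /
outlier removal, then blur and take the local variance. The variance image
is near zero both inside the (now constant) tissue body and in the
background but saturates along the tissue boundary, so thresholding it
yields a closed contour band; filling holes turns that band into the solid
slice silhouette, and the largest connected component stands in for the
interactive wand click on the dominant object.

Coordinates are pixel centers with the origin at the top-left pixel,
x rightward and y downward — the same convention the spatial module uses
for the distance map, so there is no half-pixel drift between stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .imageops import (
    BinaryMask,
    PipelineError,
    despeckle,
    dilate,
    downscale_average,
    fill_holes,
    gaussian_blur,
    largest_component,
    remove_outliers,
    rgb_to_hsb,
    threshold_band,
    upscale_mask,
    validate_rgb,
    variance_filter,
)


class NoTissueError(PipelineError):
    """No pixel passed the tissue saturation threshold."""


@dataclass
class TissueROI:
    """The slice-delineating region.

    ``mask`` is at full resolution (upscaled from the working scale),
    ``working_mask`` at the pipeline's working scale (default 1/4), and
    ``centroid`` is the (x, y) mean of the full-resolution foreground
    pixel coordinates.
    """

    mask: BinaryMask
    working_mask: BinaryMask
    centroid: tuple[float, float]


def roi_centroid(mask: BinaryMask) -> tuple[float, float]:
    """Arithmetic mean (x, y) of the foreground pixel-center coordinates."""
    ys, xs = np.nonzero(mask.pixels)
    if ys.size == 0:
        raise ValueError("cannot compute centroid of an empty mask")
    n = ys.size
    cx = float(xs.sum(dtype=np.int64)) / n
    cy = float(ys.sum(dtype=np.int64)) / n
    return (cx, cy)


def delineate_slice(img: np.ndarray, config: PipelineConfig | None = None) -> TissueROI:
    """Generate the tissue-delineating ROI around the renal slice.

    Raises :class:`NoTissueError` if nothing passes the saturation
    threshold (e.g. a blank slide).
    """
    cfg = config or PipelineConfig()
    img = validate_rgb(img)
    f = cfg.downscale_factor

    small = downscale_average(img, f)
    hsb = rgb_to_hsb(small)
    mask = threshold_band(hsb.saturation, cfg.saturation_min, 255, scale_factor=f)
    if mask.foreground_count() == 0:
        raise NoTissueError(
            f"no tissue detected: no pixel has saturation >= {cfg.saturation_min}"
        )

    mask = dilate(mask, cfg.roi_dilate_iterations)
    mask = despeckle(mask)
    cleaned = remove_outliers(
        mask.pixels,
        radius=cfg.roi_remove_outliers_radius,
        threshold=cfg.roi_remove_outliers_threshold,
        mode=cfg.roi_remove_outliers_mode,
    )
    blurred = gaussian_blur(cleaned, cfg.roi_gaussian_sigma)
    var = variance_filter(blurred, cfg.roi_variance_radius)
    contour = BinaryMask(
        (var > cfg.roi_variance_threshold).astype(np.uint8) * 255, scale_factor=f
    )
    filled = fill_holes(contour)
    working = largest_component(filled)
    if working.foreground_count() == 0:
        raise NoTissueError(
            "no tissue detected: variance contour empty after re-binarization "
            f"(threshold {cfg.roi_variance_threshold})"
        )

    full = upscale_mask(working, f)
    # Block downscaling cropped any trailing remainder; pad the upscaled mask
    # back out to the source dimensions with background.
    h, w = img.shape[:2]
    fh, fw = full.pixels.shape
    if (fh, fw) != (h, w):
        padded = np.zeros((h, w), dtype=np.uint8)
        padded[:fh, :fw] = full.pixels
        full = BinaryMask(padded, scale_factor=1)

    return TissueROI(mask=full, working_mask=working, centroid=roi_centroid(full))
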