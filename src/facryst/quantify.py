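"""Stages 2-3: crystal and tissue segmentation, and the content ratio.

Crystals are segmented at full scale by a narrow hue band-pass (yellow,
25-50 on the 8-bit hue axis) — hue isolates color identity independent of
intensity, which is what separates pale yellow depositions from red blood
cells — followed by iterated despeckling and a particle-size filter.

Tissue is segmented at the 1/4 working scale by a wide red-channel band
(red <= 155 keeps the pale tissue, rejects the near-white background),
filled in by dark-outlier removal so tubular lumens count as tissue
(excluding dilatation effects), consolidated by blur + saturated local
variance, and re-binarized at [254, 255].

Content is the full-scale crystal pixel count over the full-scale-equivalent
tissue pixel count (working-scale count x factor^2); the 255 binary weights
of the raw integrated densities cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .imageops import (
    BinaryMask,
    PipelineError,
    despeckle,
    downscale_average,
    gaussian_blur,
    raw_integrated_density,
    remove_outliers,
    rgb_to_hsb,
    threshold_band,
    validate_rgb,
    variance_filter,
)
from .roi import TissueROI

_STRUCT8 = np.ones((3, 3), dtype=bool)


class TissueSegmentationError(PipelineError):
    """The tissue mask came out empty."""


@dataclass
class CrystalMask:
    """Binary crystal segmentation at full scale with a particle census."""

    mask: BinaryMask
    particle_count: int
    particle_sizes: list[int] = field(default_factory=list)


@dataclass
class TissueMask:
    """Binary total-tissue segmentation at the working scale."""

    mask: BinaryMask


@dataclass
class ContentResult:
    """Crystal content of one slide as a fraction of total tissue."""

    crystal_pixels_fullscale: int
    tissue_pixels_fullscale_equivalent: float
    content_fraction: float
    content_percent: float
    image_id: str = ""


def segment_crystals(
    img: np.ndarray, roi: TissueROI, config: PipelineConfig | None = None
) -> CrystalMask:
    """Segment folic-acid crystals inside the ROI.

    An empty result is valid (e.g. a vehicle-treated slide).
    """
    cfg = config or PipelineConfig()
    img = validate_rgb(img)

    hsb = rgb_to_hsb(img)
    mask = threshold_band(hsb.hue, cfg.hue_min, cfg.hue_max, scale_factor=1)
    if cfg.min_saturation > 0:
        mask = BinaryMask(
            np.where(hsb.saturation >= cfg.min_saturation, mask.pixels, 0),
            scale_factor=1,
        )

    for _ in range(cfg.despeckle_iterations):
        mask = despeckle(mask)

    fg = mask.pixels > 0
    if cfg.min_particle_px > 0 and fg.any():
        labels, n = ndimage.label(fg, structure=_STRUCT8)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = sizes >= cfg.min_particle_px
        fg = keep[labels]

    fg &= roi.mask.pixels > 0

    labels, n = ndimage.label(fg, structure=_STRUCT8)
    sizes = np.bincount(labels.ravel())[1:] if n else np.array([], dtype=int)
    return CrystalMask(
        mask=BinaryMask(fg.astype(np.uint8) * 255, scale_factor=1),
        particle_count=int(n),
        particle_sizes=[int(s) for s in sizes],
    )


def segment_tissue(
    img: np.ndarray, roi: TissueROI, config: PipelineConfig | None = None
) -> TissueMask:
    """Segment all continuous renal tissue plus enclosed tubular lumens."""
    cfg = config or PipelineConfig()
    img = validate_rgb(img)
    f = cfg.downscale_factor

    small = downscale_average(img, f)
    red = small[..., 0]
    mask = threshold_band(red, cfg.red_min, cfg.red_max, scale_factor=f)

    # Dark-outlier removal fills small bright features (lumens, crystal
    # footprints) that punched holes in the red-band mask; large anatomic
    # voids exceed the disc scale and stay excluded.
    cleaned = remove_outliers(
        mask.pixels,
        radius=cfg.tissue_remove_outliers_radius,
        threshold=cfg.tissue_remove_outliers_threshold,
        mode="dark",
    )
    # Consolidation: the blurred mask alone would erode edges at the high
    # [254, 255] cutoff; adding half the (clipped) local variance, which
    # saturates exactly in edge and hole-rim zones, re-centers the boundary
    # on the true mask edge and bridges residual pinholes.
    blurred = gaussian_blur(cleaned, cfg.tissue_gaussian_sigma)
    var = np.clip(variance_filter(blurred, cfg.tissue_variance_radius), 0, 255)
    consolidated = np.minimum(blurred + 0.5 * var, 255.0)
    binary = (consolidated >= cfg.rebinarize_min) & (consolidated <= cfg.rebinarize_max)

    binary &= roi.working_mask.pixels > 0
    if not binary.any():
        raise TissueSegmentationError(
            "tissue segmentation failed: empty mask after re-binarization "
            f"[{cfg.rebinarize_min}, {cfg.rebinarize_max}]"
        )
    return TissueMask(mask=BinaryMask(binary.astype(np.uint8) * 255, scale_factor=f))


def compute_content(
    crystals: CrystalMask,
    tissue: TissueMask,
    roi: TissueROI,
    image_id: str = "",
) -> ContentResult:
    """Crystal content = crystal pixels / full-scale-equivalent tissue pixels.

    The crystal mask is at full scale while the tissue mask is at the
    working scale, so the tissue count is multiplied by factor^2 to put
    both raw integrated densities on a common scale before dividing.
    """
    rid_crystal = raw_integrated_density(crystals.mask.pixels, roi.mask.pixels)
    rid_tissue = raw_integrated_density(tissue.mask.pixels, roi.working_mask.pixels)
    if rid_tissue == 0:
        raise TissueSegmentationError(
            "cannot compute content: tissue raw integrated density is zero"
        )
    factor = tissue.mask.scale_factor
    crystal_px = rid_crystal / 255.0
    tissue_px_equiv = (rid_tissue / 255.0) * factor * factor
    fraction = crystal_px / tissue_px_equiv
    return ContentResult(
        crystal_pixels_fullscale=int(round(crystal_px)),
        tissue_pixels_fullscale_equivalent=tissue_px_equiv,
        content_fraction=fraction,
        content_percent=fraction * 100.0,
        image_id=image_id,
    )
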