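"""Pipeline configuration: every threshold and filter parameter in one place.

The color bands and the downscale factor come from the published macro; the
remaining knobs (sigmas, radii, iteration counts, cutoffs) are not printed
anywhere, so they are owned by the config with defaults calibrated on
synthetic fixtures (see docs/methods.md). A stable fingerprint of the
serialized config accompanies every result row so outputs are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    # --- stage 1: tissue-delineating ROI (working scale) ---
    downscale_factor: int = 4
    saturation_min: int = 15            # lower bound on the saturation map
    roi_dilate_iterations: int = 1
    roi_remove_outliers_radius: float = 2.0
    roi_remove_outliers_threshold: float = 50.0
    roi_remove_outliers_mode: str = "bright"
    roi_gaussian_sigma: float = 1.0
    roi_variance_radius: float = 2.0
    roi_variance_threshold: float = 2000.0  # re-binarize cutoff on the variance image

    # --- stage 2: crystal segmentation (full scale) ---
    hue_min: int = 25                   # yellow band on the 8-bit hue axis
    hue_max: int = 50
    min_saturation: int = 0             # 0 = hue-only criterion
    despeckle_iterations: int = 2
    min_particle_px: int = 4

    # --- stage 3: tissue segmentation (working scale) ---
    red_min: int = 0
    red_max: int = 155
    tissue_remove_outliers_radius: float = 5.0
    tissue_remove_outliers_threshold: float = 50.0
    tissue_gaussian_sigma: float = 1.0
    tissue_variance_radius: float = 2.0
    rebinarize_min: int = 254
    rebinarize_max: int = 255

    # --- spatial distribution ---
    bin_width_px: float = 250.0
    um_per_px: float | None = None      # required for physical-unit output

    # --- bookkeeping ---
    seed: int = 0
    output_dir: str = "facryst_out"

    def validate(self) -> None:
        if not (0 <= self.hue_min <= self.hue_max <= 255):
            raise ValueError(f"invalid hue band [{self.hue_min}, {self.hue_max}]")
        if not (0 <= self.red_min <= self.red_max <= 255):
            raise ValueError(f"invalid red band [{self.red_min}, {self.red_max}]")
        if self.downscale_factor < 1:
            raise ValueError("downscale_factor must be >= 1")
        if self.bin_width_px <= 0:
            raise ValueError("bin_width_px must be positive")
        if self.um_per_px is not None and self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def fingerprint(self) -> str:
        """Stable 12-hex-digit hash of the full parameter set."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
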