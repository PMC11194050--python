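"""Seeded synthetic whole-slide generator with exact ground truth.

Renders the appearance model the segmentation pipeline assumes: a pale,
weakly saturated tissue ellipse on a near-white background, optionally with
a central void (renal pelvis) and small bright lumens; yellow crystal
depositions, either multiglobular (overlapping globules) or diffuse
(weakly saturated speckle); red-blood-cell discs whose hue sits near the
red origin, far from the yellow band; and a near-achromatic blob emulating
undissolved embedding-compound artifacts. Per-channel Gaussian noise is
added last and clipped to 8 bits.

Rendering is integer-deterministic before noise and the noise is drawn from
a seeded generator, so identical (spec, seed) yields bit-identical slides.
Every feature's exact pixel footprint is recorded as a ground-truth mask,
which is what makes the pipeline testable without any real microscopy data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imageops import BinaryMask, hsb_to_rgb
from .roi import roi_centroid


class GenerationError(Exception):
    """The requested feature layout cannot be rendered."""


# ---------------------------------------------------------------------------
# specs


@dataclass
class TissueSpec:
    """Elliptical tissue silhouette; axes are semi-axes in pixels."""

    center: tuple[float, float] | None = None  # None -> image center
    axes: tuple[float, float] = (820.0, 680.0)
    color: tuple[int, int, int] = (150, 140, 165)  # pale gray-violet, red <= 155
    void_radius: float = 0.0  # central pelvis-like void
    lumen_count: int = 0
    lumen_radius: float = 6.0
    lumen_color: tuple[int, int, int] = (248, 246, 246)


@dataclass
class CrystalClusterSpec:
    """A family of crystal clusters sharing mode, color and placement.

    ``placement`` is one of:
      {"kind": "uniform"}                      — anywhere in the tissue
      {"kind": "fixed_radius", "radius": r}    — at radius r, random angle
      {"kind": "ring", "mean": r, "sd": s}     — Gaussian ring around centroid
    """

    mode: str = "multiglobular"  # or "diffuse" / "square"
    radius_px: float = 14.0      # cluster extent
    count: int = 1               # number of clusters in this family
    hue: int = 43                # 8-bit hue, must lie in the yellow band
    saturation: int = 180
    brightness: int = 230
    placement: dict = field(default_factory=lambda: {"kind": "uniform"})


@dataclass
class RbcSpec:
    count: int = 0
    radius: float = 6.0
    color: tuple[int, int, int] = (190, 35, 45)  # hue ~ 252, far from yellow


@dataclass
class OctSpec:
    enabled: bool = False
    radius: float = 25.0
    color: tuple[int, int, int] = (243, 243, 247)  # near-achromatic


@dataclass
class SynthSpec:
    height: int = 2048
    width: int = 2048
    tissue: TissueSpec = field(default_factory=TissueSpec)
    crystals: list[CrystalClusterSpec] = field(default_factory=list)
    rbc: RbcSpec = field(default_factory=RbcSpec)
    oct_artifact: OctSpec = field(default_factory=OctSpec)
    background: tuple[int, int, int] = (250, 250, 252)
    noise_sd: float = 3.0
    seed: int = 0

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        if "tissue" in d:
            t = dict(d["tissue"])
            for k in ("center", "axes", "color", "lumen_color"):
                if k in t and t[k] is not None:
                    t[k] = tuple(t[k])
            d["tissue"] = TissueSpec(**t)
        if "crystals" in d:
            d["crystals"] = [CrystalClusterSpec(**dict(c)) for c in d["crystals"]]
        if "rbc" in d:
            r = dict(d["rbc"])
            if "color" in r:
                r["color"] = tuple(r["color"])
            d["rbc"] = RbcSpec(**r)
        if "oct_artifact" in d:
            o = dict(d["oct_artifact"])
            if "color" in o:
                o["color"] = tuple(o["color"])
            d["oct_artifact"] = OctSpec(**o)
        if "background" in d:
            d["background"] = tuple(d["background"])
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def validate(self) -> None:
        cx, cy = self.tissue.center or (self.width / 2.0, self.height / 2.0)
        a, b = self.tissue.axes
        if not (cx - a >= 0 and cx + a <= self.width and cy - b >= 0 and cy + b <= self.height):
            raise GenerationError(
                f"tissue ellipse (center ({cx}, {cy}), axes ({a}, {b})) "
                f"does not fit a {self.height} x {self.width} image"
            )
        for fam in self.crystals:
            if not (25 <= fam.hue <= 50):
                raise GenerationError(
                    f"crystal hue {fam.hue} outside the yellow band [25, 50]"
                )
            if fam.mode not in ("multiglobular", "diffuse", "square"):
                raise GenerationError(f"unknown crystal mode {fam.mode!r}")


@dataclass
class SynthSlide:
    image: np.ndarray
    truth_tissue: BinaryMask
    truth_crystals: BinaryMask
    truth_rbc: BinaryMask
    true_centroid: tuple[float, float]
    true_content_fraction: float
    spec: SynthSpec


# ---------------------------------------------------------------------------
# rendering helpers


def _disc_footprint_at(shape, cx, cy, r):
    """Bool mask of the disc |p - (cx, cy)| <= r, clipped to the image."""
    h, w = shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return None, None
    xx = np.arange(x0, x1, dtype=np.float64)[None, :] - cx
    yy = np.arange(y0, y1, dtype=np.float64)[:, None] - cy
    local = xx * xx + yy * yy <= r * r
    return (slice(y0, y1), slice(x0, x1)), local


def _paint(img, mask_total, sl, local, color, clip_to=None):
    if sl is None:
        return
    if clip_to is not None:
        local = local & clip_to[sl]
    region = mask_total[sl]
    region |= local
    img[sl][local] = color


def _ellipse_mask(shape, center, axes):
    h, w = shape
    cx, cy = center
    a, b = axes
    xx = (np.arange(w, dtype=np.float32) - np.float32(cx)) / np.float32(a)
    yy = (np.arange(h, dtype=np.float32) - np.float32(cy)) / np.float32(b)
    return xx[None, :] ** 2 + yy[:, None] ** 2 <= 1.0


def _sample_center(rng, spec: SynthSpec, placement: dict, margin: float):
    """Sample a cluster center inside the tissue (eroded by ``margin``)."""
    cx, cy = spec.tissue.center or (spec.width / 2.0, spec.height / 2.0)
    a, b = spec.tissue.axes
    a_in, b_in = a - margin, b - margin
    if a_in <= 0 or b_in <= 0:
        raise GenerationError("cluster radius exceeds the tissue axes")
    void_out = spec.tissue.void_radius + margin if spec.tissue.void_radius > 0 else 0.0

    kind = placement.get("kind", "uniform")
    for _ in range(1000):
        if kind == "uniform":
            # uniform over the ellipse via uniform disc scaled to the axes
            u = rng.uniform(0, 1)
            theta = rng.uniform(0, 2 * np.pi)
            r = np.sqrt(u)
            px, py = cx + a_in * r * np.cos(theta), cy + b_in * r * np.sin(theta)
        elif kind == "fixed_radius":
            theta = rng.uniform(0, 2 * np.pi)
            rr = placement["radius"]
            px, py = cx + rr * np.cos(theta), cy + rr * np.sin(theta)
        elif kind == "ring":
            theta = rng.uniform(0, 2 * np.pi)
            rr = rng.normal(placement["mean"], placement["sd"])
            px, py = cx + rr * np.cos(theta), cy + rr * np.sin(theta)
        else:
            raise GenerationError(f"unknown placement kind {kind!r}")
        inside = ((px - cx) / a_in) ** 2 + ((py - cy) / b_in) ** 2 <= 1.0
        if inside and (void_out == 0.0 or (px - cx) ** 2 + (py - cy) ** 2 > void_out**2):
            return px, py
    raise GenerationError(
        f"could not place a cluster with {kind!r} placement inside the tissue"
    )


# ---------------------------------------------------------------------------
# generator


def generate_slide(spec: SynthSpec) -> SynthSlide:
    """Render a slide and its exact ground-truth masks; fully seeded."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    shape = (h, w)

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.background

    center = spec.tissue.center or (w / 2.0, h / 2.0)
    truth_tissue = _ellipse_mask(shape, center, spec.tissue.axes)
    if spec.tissue.void_radius > 0:
        xx = np.arange(w, dtype=np.float32) - np.float32(center[0])
        yy = np.arange(h, dtype=np.float32) - np.float32(center[1])
        void = xx[None, :] ** 2 + yy[:, None] ** 2 <= spec.tissue.void_radius**2
        truth_tissue &= ~void
    img[truth_tissue] = spec.tissue.color

    # small bright lumens: painted light but still tissue ground truth
    for _ in range(spec.tissue.lumen_count):
        px, py = _sample_center(rng, spec, {"kind": "uniform"}, spec.tissue.lumen_radius + 2)
        sl, local = _disc_footprint_at(shape, px, py, spec.tissue.lumen_radius)
        if sl is not None:
            keep = local & truth_tissue[sl]
            img[sl][keep] = spec.tissue.lumen_color

    # crystals
    truth_crystals = np.zeros(shape, dtype=bool)
    tissue_area = int(truth_tissue.sum())
    requested = sum(np.pi * f.radius_px**2 * f.count for f in spec.crystals)
    if requested > 0.5 * tissue_area:
        raise GenerationError(
            f"requested crystal area ({requested:.0f} px) exceeds half the "
            f"tissue area ({tissue_area} px)"
        )
    for fam in spec.crystals:
        color = hsb_to_rgb(fam.hue, fam.saturation, fam.brightness)
        for _ in range(fam.count):
            ccx, ccy = _sample_center(rng, spec, fam.placement, fam.radius_px)
            if fam.mode == "multiglobular":
                g = max(3.0, fam.radius_px * 0.45)
                n_glob = 6
                for _ in range(n_glob):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0, max(fam.radius_px - g, 0.0))
                    gx, gy = ccx + rad * np.cos(ang), ccy + rad * np.sin(ang)
                    sl, local = _disc_footprint_at(shape, gx, gy, g)
                    _paint(img, truth_crystals, sl, local, color, clip_to=truth_tissue)
            elif fam.mode == "square":
                # axis-aligned square of side radius_px; exact pixel count
                side = int(round(fam.radius_px))
                y0 = int(round(ccy)) - side // 2
                x0 = int(round(ccx)) - side // 2
                sl = (slice(max(y0, 0), min(y0 + side, h)),
                      slice(max(x0, 0), min(x0 + side, w)))
                local = np.ones(
                    (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start), dtype=bool
                )
                _paint(img, truth_crystals, sl, local, color, clip_to=truth_tissue)
            else:  # diffuse: weakly saturated speckle
                for _ in range(12):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0, fam.radius_px)
                    gx, gy = ccx + rad * np.cos(ang), ccy + rad * np.sin(ang)
                    sl, local = _disc_footprint_at(shape, gx, gy, 3.0)
                    _paint(img, truth_crystals, sl, local, color, clip_to=truth_tissue)

    # red blood cells: disjoint from crystals
    truth_rbc = np.zeros(shape, dtype=bool)
    for _ in range(spec.rbc.count):
        for _attempt in range(100):
            px, py = _sample_center(rng, spec, {"kind": "uniform"}, spec.rbc.radius)
            sl, local = _disc_footprint_at(shape, px, py, spec.rbc.radius)
            if sl is not None and not (local & truth_crystals[sl]).any():
                _paint(img, truth_rbc, sl, local, spec.rbc.color, clip_to=truth_tissue)
                break
        else:
            raise GenerationError("could not place an RBC disc off the crystals")

    # OCT-compound artifact: one lobed, low-saturation blob
    if spec.oct_artifact.enabled:
        for _attempt in range(100):
            px, py = _sample_center(rng, spec, {"kind": "uniform"}, spec.oct_artifact.radius)
            sl, local = _disc_footprint_at(shape, px, py, spec.oct_artifact.radius)
            if sl is not None and not (local & (truth_crystals | truth_rbc)[sl]).any():
                blob = np.zeros(shape, dtype=bool)
                for _ in range(4):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0, spec.oct_artifact.radius * 0.6)
                    bx, by = px + rad * np.cos(ang), py + rad * np.sin(ang)
                    bsl, blocal = _disc_footprint_at(
                        shape, bx, by, spec.oct_artifact.radius * 0.6
                    )
                    _paint(img, blob, bsl, blocal, spec.oct_artifact.color)
                blob &= ~(truth_crystals | truth_rbc)
                img[blob] = spec.oct_artifact.color
                break
        else:
            raise GenerationError("could not place the OCT artifact blob")

    # seeded per-channel Gaussian noise, clipped to 8 bits
    if spec.noise_sd > 0:
        noise = rng.standard_normal(img.shape, dtype=np.float32)
        noise *= np.float32(spec.noise_sd)
        noise += img
        np.floor(noise + np.float32(0.5), out=noise)
        img = np.clip(noise, 0, 255).astype(np.uint8)

    tissue_mask = BinaryMask(truth_tissue.astype(np.uint8) * 255, 1)
    crystal_count = int(truth_crystals.sum())
    return SynthSlide(
        image=img,
        truth_tissue=tissue_mask,
        truth_crystals=BinaryMask(truth_crystals.astype(np.uint8) * 255, 1),
        truth_rbc=BinaryMask(truth_rbc.astype(np.uint8) * 255, 1),
        true_centroid=roi_centroid(tissue_mask),
        true_content_fraction=crystal_count / tissue_area,
        spec=spec,
    )


def generate_bimodal_ring_slide(
    spec: SynthSpec,
    r1_px: float,
    r2_px: float,
    sd_px: float,
    n1: int,
    n2: int,
) -> SynthSlide:
    """Plant crystal clusters on two Gaussian rings around the tissue centroid.

    Emulates the radially bimodal deposition pattern (an inner medullary and
    an outer cortical band) so the radial histogram has two known modes.
    """
    if r1_px >= r2_px:
        raise GenerationError(f"need r1 < r2, got {r1_px} >= {r2_px}")
    a, b = spec.tissue.axes
    margin = 2 * sd_px + 20
    for r in (r1_px, r2_px):
        if r + margin > min(a, b):
            raise GenerationError(
                f"ring at radius {r} (sd {sd_px}) does not fit inside tissue axes {spec.tissue.axes}"
            )
    spec = dataclasses.replace(
        spec,
        crystals=[
            CrystalClusterSpec(
                mode="multiglobular",
                radius_px=14.0,
                count=n1,
                placement={"kind": "ring", "mean": r1_px, "sd": sd_px},
            ),
            CrystalClusterSpec(
                mode="multiglobular",
                radius_px=14.0,
                count=n2,
                placement={"kind": "ring", "mean": r2_px, "sd": sd_px},
            ),
        ],
    )
    return generate_slide(spec)


# ---------------------------------------------------------------------------
# presets: the qualitative regimes the pipeline must handle


def _content_clusters(target_fraction: float, tissue_axes: tuple[float, float]) -> list[CrystalClusterSpec]:
    """Cluster families sized so the planted area lands near the target.

    A multiglobular cluster of radius 14 covers ~400 px, a diffuse one
    ~250 px; the exact planted fraction is always read back from the truth
    masks, so this only needs to be in the right neighborhood.
    """
    area = np.pi * tissue_axes[0] * tissue_axes[1]
    target_px = target_fraction * area
    n_multi = max(1, int(round(0.7 * target_px / 400.0)))
    n_diff = max(1, int(round(0.3 * target_px / 250.0)))
    return [
        CrystalClusterSpec(mode="multiglobular", radius_px=14.0, count=n_multi),
        CrystalClusterSpec(
            mode="diffuse", radius_px=14.0, count=n_diff, hue=38, saturation=80, brightness=235
        ),
    ]


def content_slide_spec(
    target_fraction: float,
    size: int = 2048,
    seed: int = 0,
    rbc_count: int = 200,
    oct_artifact: bool = True,
    noise_sd: float = 3.0,
) -> SynthSpec:
    """Spec for a slide with a planted crystal-content fraction plus confounders."""
    axes = (0.40 * size, 0.33 * size)
    tissue = TissueSpec(axes=axes)
    return SynthSpec(
        height=size,
        width=size,
        tissue=tissue,
        crystals=_content_clusters(target_fraction, axes) if target_fraction > 0 else [],
        rbc=RbcSpec(count=rbc_count),
        oct_artifact=OctSpec(enabled=oct_artifact),
        noise_sd=noise_sd,
        seed=seed,
    )


def preset(name: str, seed: int = 0) -> SynthSpec:
    """Named study regimes: vehicle, sparse, dense, confounder_heavy, bimodal."""
    if name == "vehicle":
        return content_slide_spec(0.0, seed=seed)
    if name == "sparse":
        return content_slide_spec(0.002, seed=seed)
    if name == "dense":
        return content_slide_spec(0.05, seed=seed)
    if name == "confounder_heavy":
        return content_slide_spec(0.01, seed=seed, rbc_count=400, oct_artifact=True)
    if name == "bimodal":
        size = 4096
        return SynthSpec(
            height=size,
            width=size,
            tissue=TissueSpec(axes=(0.49 * size, 0.48 * size)),
            rbc=RbcSpec(count=100),
            oct_artifact=OctSpec(enabled=True),
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("vehicle", "sparse", "dense", "confounder_heavy", "bimodal")


def generate_preset(name: str, seed: int = 0) -> SynthSlide:
    """Render a named preset; 'bimodal' plants rings at 700 and 1800 px."""
    spec = preset(name, seed=seed)
    if name == "bimodal":
        return generate_bimodal_ring_slide(spec, 700.0, 1800.0, 50.0, n1=60, n2=60)
    return generate_slide(spec)
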