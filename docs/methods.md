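# Methods

## The measurement model

The pipeline quantifies two things on an 8-bit RGB whole-slide image of an
unstained kidney section: (i) the fraction of tissue area occupied by
folic-acid crystals, and (ii) the distribution of crystal pixels by
Euclidean distance from the slice centroid.

The image model it assumes is: a bright, near-achromatic background; a
pale, weakly saturated tissue silhouette whose red channel stays at or
below ~155; crystals that are distinctly yellow (hue between 25 and 50 on
the 8-bit hue axis, i.e. ~35°–71°) at any saturation or brightness; and
confounders that differ from crystals *in hue* — red blood cells near the
red origin, and embedding-compound remnants that are nearly achromatic and
therefore have unstable, noise-driven hue. Segmenting crystals in hue
alone is the core discriminative assumption: hue isolates color identity
from intensity, so pale diffuse depositions and saturated globules pass the
same band while erythrocytes never do. Isolated pixels whose hue is pushed
into the band by noise (this happens to achromatic pixels) are removed by
the iterated 3×3 median despeckle, which requires a 5-of-9 local majority.

### Coordinate and rounding conventions

* Pixel-center coordinates, origin at the top-left pixel center, x
  rightward, y downward. The ROI centroid and the distance map share this
  convention, so there is no half-pixel drift between stages.
* 8-bit outputs round half up; `downscale_average` means over exact
  factor×factor blocks and crops trailing remainder rows/columns.
* Neighborhood filters replicate edge pixels; disc neighborhoods contain
  offsets with `dx² + dy² ≤ r²`; the median of an even-sized window is the
  upper-middle order statistic.
* The hue scale is 0–255 (pure yellow 60° → 43 after half-up rounding);
  the crystal band [25, 50] and all other bands are inclusive at both ends.
* The distance map uses 32-bit float arithmetic (ramp images minus centroid,
  squared, summed, square-rooted), accurate to ≲1e-4 px at slide scales.
* Histogram bins are half-open `[k·w, (k+1)·w)`; a pixel exactly on an edge
  belongs to the upper bin. The bin count is `floor(max ROI distance / w) + 1`
  so that the edge case "maximum distance is an exact multiple of w" still
  conserves every pixel: the sum of counts equals the ROI-restricted
  crystal pixel count exactly, always.
* Bin membership is decided by consulting the crystal mask, never by
  testing the masked distance image against zero — the value encoding
  conflates "non-crystal" with "distance 0", and the data model must not
  inherit that ambiguity. Crystal pixels at the centroid count in bin 0.

## Pipeline stages and parameters

Stage 1 (ROI) runs at 1/4 scale: saturation threshold → dilate → despeckle
→ bright-outlier removal → Gaussian blur → local variance → re-binarize →
fill holes → keep the largest 8-connected component → upscale ×4. The
variance image is the delineation trick: after cleaning, the mask is
constant inside the slice and in the background, so variance is high only
along the tissue boundary; thresholding it yields a closed contour whose
hole-fill is the solid slice silhouette. The largest-component step stands
in for an interactive wand click on the dominant object, which the
aggressive preprocessing is designed to guarantee.

Stage 3 (tissue) re-binarizes at the high cutoff [254, 255], which on a
blurred 0/255 mask would erode every edge by ~2.6σ. The consolidation step
therefore adds half the (clipped-to-255) local variance to the blurred
mask before thresholding: the variance term saturates exactly in edge and
hole-rim zones, which re-centers the recovered boundary on the true mask
edge (empirically within ±0.6% of tissue area on default-geometry
fixtures) and bridges residual pinholes, while large anatomic voids — far
wider than the filter scales — stay excluded. Tubular lumens are folded
into the mask earlier by *dark*-outlier removal (radius 5 at working
scale ≈ 20 full-resolution px), so dilated tubules do not deflate the
content denominator.

Parameters. Color bands and scales are fixed by the method definition:
hue band [25, 50]; red band [0, 155]; re-binarize [254, 255]; downscale
factor 4; histogram bin width 250 px. The remaining knobs are not part of
the method's definition and are config-owned; defaults were calibrated
once on synthetic fixtures and then frozen:

| parameter | default | role |
|---|---|---|
| `saturation_min` | 15 | tissue-vs-background cut on the saturation map |
| `roi_dilate_iterations` | 1 | pre-thickening before despeckle |
| `roi_remove_outliers_*` | r=2, t=50, bright | stray-speck removal at working scale |
| `roi_gaussian_sigma` | 1.0 | contour smoothing before the variance step |
| `roi_variance_radius` | 2.0 | boundary-variance support |
| `roi_variance_threshold` | 2000 | contour re-binarization (peak ≈ 11 000) |
| `despeckle_iterations` | 2 | minimum that removes 1–2 px hue speckle |
| `min_particle_px` | 4 | particle-size floor; no shape filter (crystals are both multiglobular and diffuse) |
| `min_saturation` | 0 | optional saturation floor; 0 keeps the criterion hue-only |
| `tissue_remove_outliers_*` | r=5, t=50, dark | lumen/crystal-hole filling at working scale |
| `tissue_gaussian_sigma` / `variance_radius` | 1.0 / 2.0 | consolidation support |
| `bin_width_px` | 250 | radial histogram resolution |
| `um_per_px` | unset | required for mm output; scanner scale is acquisition metadata |

The crystal mask is restricted to the ROI *after* despeckling and particle
analysis, matching the order in which the selection is restored in the
measurement protocol. The ×16 tissue-count correction makes the content a
true fraction of common-scale pixel counts; measuring tissue at working
scale or on a re-upscaled mask is equivalent by construction.

## The synthetic slide generator

`synthslide` renders exactly the appearance model the pipeline assumes and
returns pixel-exact truth masks, a true centroid and a true content
fraction. Defaults define the study conditions used throughout the tests:
2048² slides (4096² for the radial-ring regime) with a tissue ellipse of
semi-axes 0.40/0.33 of the slide, crystal clusters of radius 14 px
(multiglobular: six overlapping globules of radius ~6 px, saturated yellow
hue 43; diffuse: twelve radius-3 specks at low saturation, hue 38), 200
red-blood-cell discs of radius 6 px, one low-saturation artifact blob of
radius 25 px, and i.i.d. per-channel Gaussian noise with σ = 3 — the
simplest noise model that stresses the thresholds without modeling a
scanner. Content-targeted specs size the cluster count from the analytic
tissue area; the exact planted fraction is always read back from the truth
masks, so approximate targeting introduces no bias in recovery tests.
Rendering is integer-deterministic before noise and all randomness flows
from one seeded generator, so identical (spec, seed) gives bit-identical
slides across runs and platforms.

What the generator does **not** emulate: real histology texture, stain
variability, optical defocus and shading, stitching seams, 16-bit depth,
multi-slice slides, and crystals with out-of-band hue. Passing tests
therefore demonstrate that the implementation performs the defined
measurement correctly under its stated appearance model — not that the
color thresholds themselves generalize to arbitrary scanners; on real
material those remain calibration quantities, which is why every one of
them is config-exposed and fingerprinted into the output.

## Validation design

Every pixel-level primitive is pinned to an independent brute-force
per-pixel oracle (explicit loops, clamped-index edge replication, sorted
windows) on ~100 random images up to 64×64, exactly for integer operations
and to ≤1e-4 for the distance map. Pipeline-level checks use the
generator's ground truth: ROI area within 5% of the tissue hull on
default-geometry confounder-free slides; recovered content within 10%
relative of planted fractions 0.2/1/5% under full confounding (empirically
≲2%); zero measured content on crystal-free confounder slides; the two
dominant radial bins recovering rings planted at 700 and 1800 px on 4096²
slides; exact count conservation; exact invariance of content and
histogram under 90° image rotation; near-flat annulus density (CV ≈ 2%,
bound 15%) for uniform scatters; and byte-identical CSVs across repeated
CLI runs (floats are formatted at 6 significant digits for this reason).
Problem sizes in the test suite (512–4096 px slides) were chosen as the
smallest at which each property is meaningfully exercised.

## Known limitations

* The ROI is simply connected by construction (holes are filled); interior
  anatomical voids are excluded from the *tissue* mask instead. If a slide's
  pelvis should also be excluded from the ROI itself, that requires a
  different delineation rule.
* Content can exceed the planted fraction slightly when large crystal
  clusters punch holes in the red-band tissue mask wider than the
  dark-outlier filling scale; at 5% content this bias is ≲2% relative.
* The largest-component wand surrogate assumes one section per slide;
  multi-section slides must be cropped first.
* 8-bit RGB input only; color-profile handling and scanner-native formats
  are out of scope (convert to TIFF/PNG first).
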