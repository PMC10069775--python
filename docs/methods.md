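# Methods

## Problem

Hearing research routinely needs, for every inner (IHC) and outer (OHC)
hair cell in a cochlear whole-mount micrograph, the cell's class, its
position along the coiled organ of Corti, and the best frequency that
position implies. `haircell` implements that pipeline end to end: tiled
detection on large micrographs, duplicate merging, automated recovery of
the cochlear coil's centerline, tonotopic (Greenwood) frequency
assignment, and cochleogram generation — together with a synthetic-cochlea
generator that provides exact ground truth, so every stage is testable at
desk scale without trained network weights or imaging data.

## Pipeline

### Image handling

Images (TIFF/PNG/JPEG, 1–4 channels) are normalized to `[0, 1]` floats so
all thresholds are bit-depth independent. Multi-page stacks are collapsed
to a 2D maximum intensity projection before analysis. TIFF axis roles come
from the file's series metadata when present (C/S = channel, Z/T/I/Q =
pages); otherwise the smallest non-spatial axis of length ≤ 4 is taken as
the channel axis. Channels are never reordered; the pipeline addresses
them by role (`cell_body`, e.g. anti-MYO7A; `bundle`, e.g. phalloidin).
Resampling to the working resolution uses bilinear interpolation and is a
no-op within 1% of unity scale.

### Tiling

Detection runs on square crops (default 256 px) with 10% overlap per edge:
`stride = floor(tile_size × 0.9)`. The final tile on each axis is clamped
to the image edge (larger overlap there, never padding), so tiles lie
fully inside the image, their union covers every pixel, and any object
smaller than the overlap margin is fully contained in at least one tile.
Tiles without supra-threshold signal can optionally be skipped
(`min_intensity` 0.05, `min_fraction` 0.01; off by default, since skipping
trades recall at ribbon edges for speed).

### Detection backends

Backends satisfy one contract — tile in, list of
(box, IHC/OHC label, confidence) out — so they are interchangeable.

The *reference* detector is a deterministic blob detector matched to the
synthetic generator's rendering: local maxima of the Gaussian-smoothed
bundle channel (σ default 1.5 px at the 1152 nm/px working scale) above
`min_peak` (0.2) become detections with a square box of side 4σ and score
equal to the smoothed peak height. The class label uses the biological
size/brightness asymmetry between IHC and OHC somata: the count of
supra-threshold (0.5) cell-body pixels inside the box exceeds a cutoff
(20 px² at the working scale) only for the larger, brighter IHC somata.

The *learned* backend is an adapter for a trained two-stage
region-proposal detector loaded from user-supplied weights (torch). No
training code ships here; without usable weights the adapter raises a
configuration error pointing at the reference backend.

### Merging

Tile-local detections are translated to global coordinates, thresholded
on confidence, and deduplicated by greedy non-maximum suppression at a
box-overlap threshold of IoU ≥ 0.30 (the standard reading of a "30% box
overlap" duplicate criterion). NMS is class-agnostic — cross-tile
duplicates of one physical cell occasionally differ in class and must
survive exactly once — and ties in score keep the earlier detection, for
determinism. An optional post-path filter removes detections farther than
`max_path_distance_um` (default 40 µm when enabled — comfortably beyond
the organ-of-Corti ribbon half-width) from the estimated path; it is off
by default and only meaningful for whole-coil analyses.

### Cochlear path estimation

1. **Mask.** The cell-body channel is thresholded (Otsu by default; the
   threshold is exposed because a poor setting is the known failure mode).
2. **Downsample.** Local averaging by a factor of 10; a block is
   foreground when its occupancy exceeds 0.05.
3. **Morphology.** Binary closing (disk radius 2) bridges gaps between
   somata; erosion (radius 1) sheds speckle from nonspecific staining.
4. **Centering and polar conversion.** Foreground pixels are converted to
   (angle, radius) about a center. The plain centroid is biased toward the
   coil's outer turns, which makes the per-turn radius wobble; when the
   coil wraps the full circle the center is therefore seeded from the
   spiral's inner hole (deepest background pixel, by euclidean distance
   transform, that sees foreground in every direction) and refined by a
   damped fixed-point iteration: regress radius on
   `[1, θ_unwrapped, sin θ, cos θ]` — a center offset `(Δrow, Δcol)`
   appears exactly as the sinusoid `Δrow·sinθ + Δcol·cosθ` — and absorb
   the fitted sinusoid into the center. This converges to sub-pixel
   accuracy in a few iterations. For partial coils the centroid stands.
   Angles are measured from the +col axis toward the +row axis.
5. **Unwrapping.** A coil subtending less than one turn leaves an empty
   angular sector; the largest circular gap (if > 20°) triggers a
   one-period shift of the angles below it, giving a continuous domain.
   Coils of more than one turn make the radius *multivalued* in raw angle,
   which no single shift can repair; since the radius of an
   outward-coiling ribbon grows monotonically along the coil, sorting
   points by radius orders them along the spiral, and each raw angle is
   lifted by the 2π multiple nearest the running median (window 25) of its
   predecessors' continuous angles. This handles 1–4 turns and degrades
   gracefully to the single-turn case.
6. **Gaussian-process fit.** Radius is regressed on unwrapped angle with
   a GP (constant × squared-exponential kernel + white noise;
   hyperparameters by marginal-likelihood optimization; at most 500
   seeded-subsample points, keeping the fit O(seconds)). Predictions on a
   2,000-point uniform angle grid spanning the observed range convert back
   to cartesian and are rescaled to full resolution (block centers map to
   `10·x + 4.5`), giving the centerline polyline with cumulative arc
   length in µm.
7. **Apex inference.** Discrete three-point (circumradius) curvature is
   averaged over the terminal 10% of vertices at each end; the tighter
   curl is the apex — the flat-mounted cochlea curls most tightly at its
   apical, low-frequency end. A relative difference below 5% raises a tie
   flag, defaults the apex to the first point, and marks the run for
   manual review. `swap_apex` flips the designation (an involution).
   Finalized paths are stored apex-first with `cumulative_um[0] = 0`.

Manual paths (CSV of `x,y` pixel coordinates, traced base→apex in the
ImageJ-plugin convention, so the file's last point is the apex) replace
steps 1–7 entirely, including in the multi-piece workflow.

Cells are projected onto the polyline by point-to-segment distance; the
projection foot's arc-length fraction from the apex gives the percent
position, the perpendicular distance feeds the optional path filter.

### Frequency assignment and cochleograms

Best frequency follows the Greenwood map
`F(x) = A(10^{a·x} − k)` Hz with `x` the fraction of cochlear length from
the apex. The constants are species presets (overridable):

| species | A (Hz) | a | k | F(0)–F(1) |
|---|---|---|---|---|
| mouse (default) | 9800 | 0.92 | 0.68 | 3.1–74.9 kHz |
| human | 165.4 | 2.1 | 0.88 | 0.02–20.7 kHz |
| guinea pig | 350 | 2.1 | 0.85 | 0.05–43.8 kHz |

The mouse constants are the Greenwood-form fit to the murine
place–frequency map; human and guinea pig are the classic fits.
Frequencies are reported in kHz (2 decimals in outputs); distances in µm
(1 decimal). Cochleograms histogram per-class cell counts over
percent-length bins (default 1%, anchored at the apex; half-open bins,
last bin closed), so bin totals always equal per-class cell counts.
Multi-piece runs concatenate piece arc lengths in user-declared apex→base
order — piece ordering is deliberately manual.

### Threshold tuning

`grid_search` sweeps (confidence, NMS IoU) over a `steps × steps` grid on
`[0,1]²` (default 100 steps), applying rejection then NMS to raw
detections, matching survivors to ground truth (greedy by score,
class-aware, IoU ≥ 0.5 — the community-standard criterion), and averaging
the metric `TP − FN − FP` over samples. True negatives are undefined for
detection, so the "accuracy" is the true-positive count penalized by
misses and false alarms; the metric is a pluggable function. Ties at the
maximum break toward larger thresholds (the more conservative setting).

## Synthetic generator

The generator emulates a flat-mounted neonatal cochlea at desk scale:

- **Geometry.** Archimedean spiral `r = a + bθ` (default a = 100 px,
  b = 29 px/rad, 2.25 turns) — its curvature decreases monotonically
  outward, reproducing the tighter apical curl the apex-inference rule
  relies on, and its arc length has a closed form used as exact truth.
  Working pixel size 1152 nm/px (288 nm/px imagery downscaled 4×) keeps
  the coil at its physical ≈5 mm length in a ≈1120 px image.
- **Cells.** One IHC row on the inner side (−10 µm) and three OHC rows on
  the outer side (+6/+14/+22 µm), spaced 9 µm (IHC) and 8 µm (OHC) along
  the arc with 0.4 µm jitter — realistic murine counts (≈620 IHC,
  ≈1,870 OHC). Each cell records its exact arc position, percent from
  apex, and Greenwood frequency; dropout simulates hair-cell loss and
  records the removals.
- **Rendering.** The soma channel is a contiguous ribbon of overlapping
  Gaussian blobs (IHC σ 3.2 µm, amplitude 1.0; OHC σ 2.0 µm, amplitude
  0.7); the bundle channel renders separated per-cell blobs (IHC σ 2.0 µm
  > OHC σ 1.4 µm). Ground-truth boxes are 4σ squares around bundle
  centers. Additive Gaussian noise (σ 0.05) and optional off-coil
  distractor blobs (recorded separately in the truth) complete the image.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: anisotropic PSFs and depth attenuation,
nonspecific staining textures, tissue tears and mounting distortion,
phalangeal scars, the fourth OHC row, and real detector confidence
statistics. The reference detector is matched to this rendering; results
on real micrographs depend on a trained learned backend and are out of
scope for the synthetic validation.

## Numerical choices and degenerate inputs

- Rescale no-op band: 1% of unity; intensity stretch of a constant
  channel returns zeros with a warning rather than an error.
- NMS and grid search are fully deterministic (stable sorts, explicit tie
  rules).
- GP failure (singular kernel, non-finite or non-positive predicted
  radii) raises a path-estimation error advising manual annotation, as
  does an empty or near-empty foreground (< 10 pixels).
- A circle input (no curl asymmetry) trips the apex tie flag instead of
  guessing.
- Generator parameters whose turn spacing is below the rendered ribbon
  width are rejected as self-intersecting.
- Seeds: every stochastic step (GP subsample, generator) takes an explicit
  seed; identical seeds give bit-identical outputs.

## Validation experiment sizes

The self-validation suite uses 10 seeded default-condition cochleae for
the frequency-fidelity experiment (≈2,430 cells each), 20 seeded noisy
spirals (2–4 turns, 5% radial noise) for arc-length recovery, 100
randomized spirals for apex inference, and 1,000 random 50-box instances
for the NMS/brute-force equivalence — sizes chosen to exercise every
multi-turn regime while keeping a full run on one CPU in minutes.

## Known limitations

- The radius-guided unwrap assumes the coil's radius grows monotonically
  along its length; strongly non-spiral mounts (S-shaped dissections)
  need manual paths.
- Class-agnostic NMS can, in principle, let a high-confidence false class
  suppress a correct duplicate; at the observed duplicate rates this is
  negligible.
- The grid-search metric is not average precision; it is the simple
  count-based accuracy described above, exposed as a pluggable function.
- Missing-cell (scar) detection is not attempted; dropout in the
  generator only thins the rendered rows.
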