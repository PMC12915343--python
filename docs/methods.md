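# Methods

This note documents the measurement model, the defaults that matter, and
the design choices made where the procedure was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Detection

**Classical backend.** An optional per-channel linear stretch
v′ = clamp(round(255·(v−lo)/(hi−lo)), 0, 255) (rounding half away from
zero; identity at (0, 255)) is followed by conversion to
hue/saturation/brightness via the standard hexcone model: bri =
max(R,G,B)/255, sat = (max−min)/max (0 for black), hue ∈ [0, 1) with red
at 0. Achromatic pixels take hue 0. A pixel passes a class gate when its
hue lies in [hue_lo, hue_hi] (wrapping through 1.0 when hue_lo > hue_hi,
which is how the red class straddles hue 0), sat ≥ sat_min and
bri ≥ bri_min. Gated pixels are grouped into 8-connected particles;
particles outside [min_area_px, max_area_px] are discarded as noise or
non-nodular structure. Default gates:

| class | hue | sat_min | bri_min |
| --- | --- | --- | --- |
| CYAN | 0.42–0.58 | 0.3 | 0.15 |
| YELLOW | 0.10–0.20 | 0.3 | 0.15 |
| RED | 0.92–0.06 (wrapped) | 0.3 | 0.15 |

Real imagery needs per-image gate tuning (the thresholds used in any
given study are never universal); all gates are config-overridable.

**Imported backend.** Prediction files carry class name, a center-based
box (x=col, y=row), a confidence, and optionally a segmentation polygon.
Box conversion is row_min = round(y − h/2), col_min = round(x − w/2),
half-open extents round(h) × round(w), rounding half away from zero,
clipped to the image. Polygons are rasterized by pixel-center inclusion
under the even-odd rule, with centers exactly on an edge counted inside;
the bounding box of a polygon detection is re-derived from the mask so
that the "bbox = tight box of mask" invariant holds for every detection.
Default class aliases: Cyan/Blue → CYAN, Yellow → YELLOW, Red → RED.

**Shared post-processing.** Detections with confidence below the
threshold (default 0.3, comparison inclusive — a detection at exactly
0.30 survives) are dropped. The classical backend has no model
confidence, so it scores each particle by its mean HSB brightness, making
the same filter meaningful for both backends. Detections of *different*
classes whose mask overlap covers at least `mixed_overlap_frac` (default
0.5) of the smaller mask merge into one MIXED nodule (union mask, max
confidence, partner classes recorded); merging is transitive via
union-find and idempotent. Same-class overlaps never merge — they are
segmentation duplicates, not mixed infections.

## Photometry and morphometry

Brightness is measured on the **bounding-box crop** of the original RGB
image, not the mask — this mirrors the crop-then-average procedure the
pipeline reproduces; a mask-based alternative exists behind
`mask_brightness: true` but is off by default and excluded from
acceptance checks. Channel rules: the cyan reporter emits in the blue
channel, so CYAN brightness is the blue-channel mean; yellow and red
reporters have mixed-spectrum emission, quantified as the mean of the
red-channel mean and the *yellow pseudo-channel* mean, where the yellow
channel of an RGB image is defined per pixel as (R+G)/2 (RGB has no
native yellow plane; this is the standard projection). MIXED nodules take
the maximum over their partner-class rules, and are flagged in all
outputs. Raw 8-bit values map linearly to 0–100 (·100/255); only 8-bit
inputs are accepted, precisely so this normalisation is exact.

Projected area is the mask pixel count (px²), converted to mm² as
area · pixel_size_mm²; distances convert as dist · pixel_size_mm. The
default pixel size 1.0 mm means uncalibrated outputs equal pixel units
numerically. Centroids are unweighted means of mask coordinates.

## Root network and distances

1. **Segmentation**: mean-channel grayscale, Otsu's between-class-variance
   threshold on the 256-bin histogram (deterministic, parameter-free —
   chosen because plain "thresholding" leaves the method open), then
   morphological closing followed by opening with a disc of radius
   `morph_radius_px` (default 2; removes sub-element speckle, so real
   structures must be ≳ 5 px wide to survive).
2. **Nodule exclusion**: detection masks are set to background, isolating
   the root network.
3. **Proximity filter**: foreground farther than `proximity_px` (default
   20, configurable — the defined proximity is a free parameter) from the
   root structure is removed as noise. The structure is the largest
   8-connected component of the *pre-exclusion* mask: carving nodules out
   can bisect the root, and measuring proximity to one fragment would
   discard the other half of the root system.
4. **Primary root**: distances are measured to the primary root (the main
   axis), not to the whole root system — a nodule sitting on a lateral
   should be credited with the path length along that lateral. The
   primary region is the largest component of a morphological opening
   with radius `primary_open_radius_px` (default 3): the opening erases
   any structure thinner than its disc (laterals), leaving the dominant
   main-root body. It is computed before nodule exclusion so on-primary
   nodules stay attached to it and score exactly 0. The default assumes
   the primary root is rendered/imaged distinctly wider than laterals;
   the radius must be tuned to the image scale.
5. **Distances**: detection masks are re-inserted into the navigable set
   (never into the primary) so the search can start at the nodule
   centroid. A nodule touching the primary (overlap or 8-adjacency)
   scores 0 by construction. Otherwise Dijkstra runs from the navigable
   pixel nearest the centroid (ties: smaller row, then column) over the
   8-connected grid with octile weights — 1 for axis steps, √2 for
   diagonals — stopping at the first primary pixel. The octile metric was
   chosen over unit-step BFS because it approximates physical path length
   (it dominates the Euclidean lower bound and overestimates it by at
   most ≈ 8%). Distances are network-internal: no Euclidean gap between
   the centroid and its attach pixel is added. Unreachable nodules
   (isolated islands, or an empty root mask) are reported as such rather
   than given a number.

## Aggregation

Per-image summaries report, for each class in the fixed order CYAN,
YELLOW, RED, MIXED, the nodule count, total and mean projected area (px²
and mm²) and total and mean brightness; zero-count classes get explicit
zero rows (flagged by n = 0) to keep tables rectangular. Occupancy
percentages divide per-class counts by labelled + unlabelled nodules;
dark (fluorescence-free) nodules cannot be detected by any fluorescence
pipeline, so their count is an external input (default 0, with a logged
warning). A MIXED nodule counts once — occupancy semantics are one nodule
= one unit. The batch driver processes files in lexicographic order,
isolates per-image failures as error rows, and has no cross-image state,
so a batch equals the union of single-image runs.

## Simulator

The generator emulates the gross structure of nodulated-root
fluorescence imagery: background gray level 10, a momentum-damped
monotone-downward primary root (width 9 px, intensity 180) spanning a
512×512 frame, laterals (width 5 px — the minimum that survives the
default morphology — length ≤ 170 px) branching at spaced positions, and
nodules as uniform discs (default radius 6 px) or squares at class peak
colours CYAN (0,200,255), YELLOW (230,220,30), RED (220,40,40), all
validated against the default gates at generation time. Optional
i.i.d. Gaussian pixel noise (the `noisy` preset uses sd 8) is the
simplest model adequate for threshold-robustness checks — it is not a
camera model. Everything derives from one seed; renders and truth files
are byte-reproducible.

Ground truth records exact masks, areas, the brightness of each nodule's
bounding box on the noise-free render (closed-form for squares, which
fill their box), and, for lateral-borne nodules, the octile arc length
along the lateral measured from where the lateral clears the *junction
zone* — the region within (root_width + lateral_width)/2 of the primary
centerline, the geometric radius at which the two tubes stop overlapping.
At the scale of the root widths the exact point where a lateral "leaves"
the primary is inherently ambiguous; this definition keeps truth purely
geometric, and the distance-recovery tolerance max(3 px, 8 % of L)
absorbs the residual junction ambiguity plus the octile overestimate.
Truth serialises in the prediction-file schema (polygon outlines traced
at the 0.5 level pass between pixel centers, so rasterization round-trips
masks exactly), which lets truth drive the imported-detection path and
the evaluator.

What the simulator does **not** model — optics (PSF, vignetting), root
autofluorescence texture, nodule developmental zonation, occlusion by
overlapping roots, JPEG artifacts — bounds what passing tests show:
correctness of the measurement pipeline under its stated model, not
robustness to real-microscope nuisance factors. Gate thresholds that are
trivially satisfied by simulated peak colours still require per-image
tuning on real data.

## Evaluation

Predictions match truth by mask IoU ≥ `iou_min` (default 0.5), class-aware,
greedy one-to-one in descending IoU (ties: lower truth index, then lower
prediction index) — the standard detection-evaluation convention.
Precision = tp/(tp+fp) and recall = tp/(tp+fn), defined as 1.0 when the
denominator is 0 (no errors possible) while a computed 0/(n>0) stays 0;
F1 is their harmonic mean, 0 when both are 0. Per-class metrics are
complemented by micro-averaged overall scores and signed count errors
(detected − truth).

## Numerical and degenerate-input conventions

- Rounding is half-away-from-zero wherever a real becomes a pixel index
  or 8-bit value.
- Constant images yield an empty root mask; all distances become
  unreachable rather than raising.
- Ties in attach-point selection and particle ordering break by (row,
  col) scan order; all outputs are deterministically ordered, and no
  stage of the analysis path consumes randomness — only the simulator
  does, from a single seed.
- Degenerate polygons (< 3 vertices or zero rasterized area) fall back to
  the declared bounding box.

## Problem sizes

Tests and the acceptance script run on 512×512 renders (15 nodules for
counting checks, 3 laterals for distance checks), 100 random 30×30
navigable masks for the geodesic oracle comparison, and 200 randomized
unit-conversion draws — sizes at which the brute-force oracles
(flood-fill labelling, Bellman–Ford relaxation, pixel-center counting,
exact rational arithmetic) remain exact and fast.

## Known limitations

- Bounding-box photometry includes background and, for nodules on the
  root, root pixels; it understates mask-pure brightness by design
  (fidelity to the reproduced procedure beats photometric purity here).
- Primary-root extraction assumes a width contrast between main root and
  laterals; on images where laterals rival the primary's width the
  opening cannot separate them and `primary_open_radius_px` must be
  adjusted (or distances read as "to the root system").
- The proximity filter can disconnect root segments beyond an excluded
  nodule from far laterals; nodules there report unreachable.
- Mixed-infection detection requires overlapping per-class masks, which
  the classical single-hue gates cannot produce; merging is effective on
  imported instance-segmentation output.
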