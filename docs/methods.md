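# Methods

This note documents the algorithms, numerical conventions, default
parameters, and the synthetic benchmark shipped with `prickle`.

## Pipeline overview

1. **Mask refinement** (`refine_mask`). The input tongue mask is reduced to
   its largest 8-connected foreground component; every background component
   that does not touch the image border (4-connectivity, evaluated on a
   1-pixel padded grid so all border-adjacent background merges into one
   exterior component) is filled. The result is a single simply-connected
   silhouette, and the operation is idempotent.

2. **Partition** (`partition_tongue`). Anatomical areas are defined on the
   refined mask row by row. With tongue rows spanning `length` rows, the top
   `f_root * length` rows (rounded to the nearest integer) are *root* and
   the bottom `f_tip * length` rows are *tip*. In the remaining body rows, a
   pixel at column `c` in a row spanning `[left, right]` is *margin* when
   `min(c - left, right - c) <= f_margin * (right - left) / 2`, else
   *center*. Defaults: `f_root=0.25`, `f_tip=0.20`, `f_margin=0.20`. The
   labels exactly cover the mask (every foreground pixel gets exactly one
   area) and the rule is mirror-symmetric in the column direction. A
   smoothed midline (symmetric moving average, window 5, shrinking evenly at
   the ends so linear midlines are preserved) is computed for orientation
   checks and diagnostics.

3. **Blob detection** (`detect_blobs`). The grayscale image (ITU-R 601 luma)
   is thresholded at every level in `arange(min_threshold, max_threshold,
   threshold_step)`; at each level the dark pixels (`pixel < t`) are
   labeled 8-connected and each component is kept if it passes the area
   window and the three shape scores (circularity, convexity, inertia
   ratio). Surviving candidates are grouped across thresholds by
   single-linkage: two candidates join when their centroids lie within
   `min_dist_between_blobs` (default 10 px). A group with at least
   `min_repeatability` members becomes a blob; its center is the mean of the
   member centroids, its reported area/scores come from the member at the
   group's lower-median threshold, and its diameter is `2 * sqrt(area/pi)`.
   Blobs are returned sorted by (y, x).

4. **Per-area parameters**. `run_pipeline` partitions the refined mask and
   routes each blob (by the area label under its center) through the
   parameter block of its area, keeping it only if it passes that block.
   The packaged default uses a tight block in root/center (where crack-like
   dark structures concentrate) and a loose block in tip and margin:

   | parameter | root_center | tip / margin |
   |---|---|---|
   | thresholds | 60..100 step 2 | 60..100 step 2 |
   | min_repeatability | 8 | 4 |
   | area | 4..25 | 2..40 |
   | circularity / convexity / inertia | 0.8 / 0.8 / 0.5 | 0.4 / 0.4 / 0.4 |
   | max chromatic aberration | 85 | 100 |

   Rationale: cracks are elongated and low-circularity but their beaded
   fragments can pass loose shape gates, so root/center additionally
   demands high repeatability (stable across 8 threshold levels) and a
   narrow area window; tip and margin rarely contain cracks, so looser
   gates preserve recall on small or partially blurred prickles.

5. **Chromatic filter** (`filter_by_aberration`). Each blob's mean RGB over
   its disk is compared against the reference prickle palette of its area
   with the redmean distance

   `sqrt((2 + rbar/256) dR^2 + 4 dG^2 + (2 + (255 - rbar)/256) dB^2)`,

   `rbar = (R1 + R2) / 2`. The blob survives if its minimum distance to any
   reference color is below the area's bound. Reference colors are supplied
   by the annotator (or exported by the synthetic generator);
   `root_center` serves as fallback palette for areas without their own.

6. **Export**. Survivors become padded square boxes (side
   `ceil(diameter) + 2 * box_pad`, clipped to the frame) and are written as
   Labelme rectangles with half-open exclusive max corners.

## Numerical conventions

- **Perimeter** — the Moore boundary trace through pixel centers
  (Jacob's stopping criterion), simplified by Douglas–Peucker with
  tolerance 0.8 px, plus 4 (one half-pixel per convex corner of an
  axis-aligned shape). An s-by-s square gets perimeter exactly `4 s`, so
  its circularity `4 pi area / perimeter^2` is exactly `pi / 4 ≈ 0.785`
  and a tight circularity gate of 0.8 separates squares from disks.
- **Convexity** — component area divided by the area of the convex hull of
  its pixel centers, clipped to `[0, 1]`; degenerate components (collinear
  pixels) score 1.0. A radius-6 digital disk scores ≈ 0.97; a 15×15 plus
  sign with 3-px arms scores `81 / 124 ≈ 0.65`.
- **Inertia ratio** — ratio of the smaller to the larger eigenvalue of the
  second central moment matrix of the pixel centers; 1.0 for a single
  pixel and for perfect disks, near 0 for thin lines.
- **Connected components** — a two-pass union-find labeler (numba-compiled)
  with labels consecutive in first-encounter raster order, validated
  against a flood-fill oracle for both 4- and 8-connectivity. Foreground
  uses 8-connectivity, background 4-connectivity (the standard duality).
- **Redmean distance** — as given above; white–black ≈ 764.83,
  red–black ≈ 403.03. Symmetric, zero exactly on equal colors.

## Evaluation

Segmentation masks are scored pixel-wise (IoU, precision, accuracy), with
`None` rather than 0 for undefined ratios. Detections are matched to
ground-truth boxes one-to-one greedily by descending IoU above a threshold
(ties broken toward the earlier ground-truth, then earlier prediction);
counts always satisfy `tp + fn = |gt|` and `tp + fp = |pred|`, and on
sparse layouts the greedy matching equals the exhaustive optimum.
`detection_report` splits counts by the area under each box's center
(root/center pooled, tip, margin, total); boxes centered on background are
logged and counted in the total only.

## Parameter tuning

`grid_search_params` tunes one area's detector block by cyclic
coordinate-wise search. Each free parameter gets an 11-value grid spanning
`0.5 x` to `1.5 x` its initial value (integer parameters rounded half-up
and de-duplicated); the objective is F1 at IoU 0.3 over the tuning scenes,
with ties resolved toward the value closest to the initial (then the
smaller). At most 5 cycles; with a single free parameter this reduces to
one exhaustive scan of the 11-point grid.

## Synthetic benchmark

`generate_scene` renders a portrait tongue (default 576 × 768, W × H) from
a seeded spec, fully deterministic (per-element
`np.random.default_rng([seed, stream])` streams; byte-identical across
runs, and changing the count of one element class does not reshuffle the
others). A scene contains:

- **prickles**: small dark plateau disks (RGB ≈ (115, 30, 42), radius
  2.0–3.2 px, soft 0.6-px rim) with per-element color jitter, placed in
  root/center, tip, and margin with weights 0.15 / 0.50 / 0.35 and minimum
  separation 12 px; the true boxes, colors, and areas are recorded;
- **crack distractors**: beaded chains of dark elliptical dashes confined
  to the root/center band — individually they pass the loose shape gates
  but fail the tight root/center gates (dash area ≈ 30 px exceeds the
  tight 25-px maximum and repeatability falls short);
- **petechiae distractors**: larger purple spots (radius 4.3–5.8) whose
  color and size fail every gate;
- **mask degradation**: seeded holes and exterior speckles that
  `refine_mask` provably removes (the degraded mask refines back to the
  clean one exactly).

Limitations: the generator uses flat backgrounds with smooth vignetting,
no specular highlights, no motion blur, and geometric idealizations of
both prickles and distractors; the reported recall/precision therefore
bound what the pipeline achieves under its own model assumptions, not
clinical performance. `fast_spec` (256 × 192, fewer elements, same
absolute feature sizes) is used in tests where full-frame realism is not
the property under test.

## Problem sizes

The shipped studies use 50 full-size scenes (suite seeds `seed..seed+49`)
for recall/precision and mask recovery, a 12-scene subset for the
partition ablation (both numbers chosen to keep the full study under a few
minutes on one core while leaving binomial noise well below the observed
margins), and two 6-spot 64 × 64 scenes for the grid-search study.
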