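# Methods

`crowneval` implements a map-based accuracy-assessment workflow for
individual tree-crown detection in high-resolution UAV imagery of
regenerating conifer plantations. The workflow evaluates a detector not by
classic bounding-box matching alone but at the level of *reference
polygons*: hand-delineated crowns of the target species ("White Pine") and
systematically constructed non-target polygons ("Other"), each classified
by whether any predicted box intersects it. This note describes the model
behind each stage, the parameters that matter, and the choices made where
the design was genuinely open.

## 1. Evaluation model

### Polygon-level confusion matrix

Let `C` be the set of target reference polygons and `O` the set of Other
polygons. For a post-processed detection set `D` (axis-aligned boxes):

- TP = #{c ∈ C : c intersects some d ∈ D}
- FN = #{c ∈ C : c intersects no d}
- FP = #{o ∈ O : o intersects some d}
- TN = #{o ∈ O : o intersects no d}

from which Precision = TP/(TP+FP), Recall = TP/(TP+FN), and
OA = (TP+TN)/(TP+FP+FN+TN). The assessment unit is the reference polygon:
row margins always equal |C| and |O|, which is what makes published
polygon-level tables reconstructible from counts. One detection may serve
several reference polygons, and several detections on one polygon count
once. "Intersects" means positive interior overlap area everywhere in the
package; boundary-only contact never matches (a configurable but
deliberate reading — edge-touching geometries are artifacts of gridded
construction, not detections of anything).

Undefined ratios (e.g., precision when TP+FP = 0) are NaN, never 0.
Reported values are rounded half-up to two decimals at the reporting layer
only. One consequence worth knowing: a matrix like (TP=412, FP=2) has
precision 0.9952, which *rounds to 1.00* at two decimals even though such
results are conventionally quoted as 0.99; the raw ratio is always
retained for this reason.

### Average precision

A separate, classic object-detection metric is provided for
detector-internal validation: detections sorted by descending confidence
are greedily matched one-to-one to reference boxes at IoU ≥ 0.5 (default),
and AP is the area under the all-points-interpolated precision–recall
curve. The interpolation variant is a choice; all-points was selected as
the current community default. The two matching regimes — plain
intersection for the confusion matrix, IoU for AP — are intentionally
distinct and must not be merged.

## 2. True-negative construction

Thematic-map accuracy needs true negatives, which detection tasks do not
naturally define. The construction here: overlay a square grid (1 m cells
by default) on the block, buffer each cell center into a disc, drop every
buffer that overlaps a reference crown, and retain `n_target` of the
survivors by seeded uniform subsampling (defaults follow the two
evaluation blocks: radius 0.5 m with 500 retained for the medium-density
case, radius 1 m with 400 for the high-density case).

Open choices, resolved as follows:

- **Radius vs diameter.** The buffer sizes are stated in the source
  protocol only as "average crown width values". Plot-level mean crown
  widths at these sites are near 1 m, so either reading is plausible; the
  values are used as *radii* and exposed as explicit configuration.
- **Thinning rule.** How survivors were reduced to exactly 500/400 is not
  documented; seeded uniform sampling is the least-assumptive choice and
  keeps the procedure reproducible. Buffers are not required to be
  mutually disjoint (1 m-spaced centers with a 1 m radius necessarily
  overlap).

The post-condition is assertable and asserted: no returned polygon has
positive overlap with any crown. If fewer than `n_target` buffers survive,
the error names the shortfall rather than silently returning fewer.

## 3. Synthetic scenes

No spatial data ships with the evaluation design, so the generator
recreates its statistical structure:

- **Stem density.** Crown centers follow a homogeneous Poisson process at
  the configured density (block values: 3657, 4744, 8796 stems/ha for the
  low-, medium-, high-density blocks). An optional perturbed planting grid
  (square spacing at the target density, jitter sd = 20 % of spacing)
  reflects the plantation origin of such stands; the truth about spatial
  pattern beyond density is unknown, so the process is configuration, not
  assertion.
- **Crown sizes.** Pixel areas (at 6 cm GSD) follow a log-normal truncated
  to [24, 1276] px whose post-truncation mean and sd are moment-matched by
  root-finding on the closed-form truncated moments to the empirical
  training-crown statistics (mean 297.43 px, sd 203.53 px). The family is
  a choice — only empirical moments and range are known — and log-normal
  is the standard right-skewed size model. Sampling is exact inverse-CDF
  on the truncated interval. Crowns are rendered as 64-gon discs with the
  radius inflated by ~0.08 % so polygon area equals the drawn area; crowns
  may overlap freely (overlap is a documented feature of dense
  regeneration), and centers are inset so every polygon lies inside the
  extent. Crowns that could not fit the extent at all are truncated to the
  largest that fits (relevant only for toy extents).
- **Detections.** Each crown independently yields its bounding-box
  envelope with probability `p_detect`, jittered in position (Gaussian,
  default sd 5 cm) and scale (log-normal, default sd 0.1). Commission
  boxes arrive as a Poisson process (`commission_per_ha`), sized like
  crowns. Confidence scores are scaled-Beta: true positives on
  [0.90, 1.00] with ~97 % of mass above the 0.95 operating threshold,
  false positives on [0.50, 1.00] with ~95 % of mass below it — so
  confidence filtering behaves qualitatively like a real detector's
  without claiming to model one. `duplicate_rate` adds redundant
  near-duplicate boxes for NMS to remove.
- **Imagery.** `rasterize_scene` renders crowns as bright discs
  (intensity ~170) and non-target vegetation as intermediate discs (~100)
  over noisy background (~60), with per-band offsets for multiband
  output. This is deliberately schematic: it supports geometric round-trip
  checks of the chip exporter, not radiometric realism.

What passing tests therefore show: the *bookkeeping* — geometry,
filtering, counting, metric arithmetic — is correct under controlled
conditions. They do not show that any detector achieves any particular
accuracy on real imagery, nor that real crown-size or spatial-pattern
distributions are log-normal/Poisson.

### A caution on parameter recovery at operational densities

With the intersection-based TP rule, measured recall is *not* the
per-crown detection probability once crowns overlap: a missed crown that
overlaps a detected neighbor's box is still counted detected. At the block
densities with the configured crown sizes this inflation is large (mean
recall ≈ 0.95–0.99 when `p_detect` = 0.82; total crown area at
8796 stems/ha is ~94 % of ground area). On sparse non-overlapping scenes
(planting grid at 400 stems/ha, 5 m spacing) recall recovers `p_detect`
to within one standard error, which isolates the bookkeeping from the
overlap effect. The acceptance suite runs both conditions and reports the
dense-scene inflation honestly; anyone interpreting polygon-level recall
on dense regeneration should treat it as an upper bound on per-crown
detectability.

## 4. Detection post-processing

Confidence filtering keeps detections with confidence ≥ τ (default 0.95;
the boundary is inclusive because the protocol excludes detections
*below* the threshold). NMS is greedy in descending confidence: a box is
kept iff its IoU with every kept box is below the threshold (default 0.5 —
the suppression rule is fixed by the design but its overlap threshold is
not stated anywhere, so 0.5 is a flagged convention). Confidence ties
break by larger area, then input order, making the output deterministic.
The default pipeline order is filter-then-NMS.

## 5. Chip export

Tiling follows the export-tool parameters: 256 px tiles, 128 px stride,
TIFF chips, PASCAL VOC XML. Window offsets step by the stride while a
full tile fits; a trailing window flush with the far edge is added when
the last step falls short, and rasters smaller than a tile yield one
zero-padded window. With rotation enabled, chips are generated at every
multiple of 45° about the raster center: each orientation tiles the
footprint in its rotated frame (bilinear resampling), and windows not
fully inside the rotated footprint are dropped. Eight orientations minus
boundary losses multiply the chip count by roughly 4–8; the reference
workflow's observed 107 → 872 expansion is consistent with this mechanism
but depends on its exact (undocumented) boundary semantics, so only the
direction — rotation strictly increases the chip count — is guaranteed or
tested. VOC coordinates are written 1-based inclusive (the classic
dialect); background-only chips are skipped by default; objects clipped at
tile edges are kept while any positive overlap remains, with a
minimum-overlap-fraction option.

## 6. Field plots

Fixed-area plot tallies (every stem ≥ 0.3 m tall; the filter is applied at
ingestion, as in the field protocol) are expanded to density as
`mean count × expansion factor × 2.471` (plots-to-acre factors 500/200/200
for the high/medium/low-density blocks; 2.471 acres/ha). Summaries report
mean, median, sd (n−1), min, max, with plot counts summarized both as
stems/plot and as expanded stems/ha under separate, explicitly labeled
rows — the two units are never mixed in one row.

## 7. Numerical and reproducibility choices

- Disc buffers use 64 segments (area within 0.2 % of πr²; the contract is
  1 %).
- Grids cover their extent by ceiling division per axis, anchored at the
  extent's min corner (no origin is specified by the protocol).
- All stochastic stages take explicit `numpy` Generators; the pipeline
  driver fans one global seed out through `SeedSequence.spawn`, so any
  stage re-run from persisted intermediates reproduces downstream outputs
  bit-for-bit, and repeat runs give byte-identical JSON reports.
- All geometry lives in one projected CRS in meters, carried as an opaque
  tag; CRS mismatch between layers is a refusal, never a silent
  reprojection.
- Problem sizes in the test and acceptance runs (12 × 12 m replicate
  scenes, 100–200 replicates, 1 ha density checks, 64 px toy chips) were
  chosen to estimate each quantity to well within its comparison
  tolerance while keeping a full run in seconds to minutes.

## 8. Known limitations

- The rendered imagery is schematic; nothing radiometric can be validated
  against it.
- Crown shapes are discs; real crowns are irregular and the envelope-box
  detection surrogate inherits that simplification.
- The rotation-export chip counts of any particular GIS tool are not
  exactly reproducible (boundary semantics undocumented); only directional
  behavior is guaranteed.
- Polygon-level recall on dense stands conflates per-crown detectability
  with crown overlap (see §3); this is a property of the assessment
  design itself, faithfully reproduced.
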