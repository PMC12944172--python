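# crowneval

Accuracy assessment for UAV-based detection of regenerating conifer
crowns — the evaluation side of an individual-tree-detection workflow,
usable without imagery or a trained model.

Detecting young regeneration (trees ≥ 0.3 m tall re-establishing after
harvest) in 6 cm ground-sampling-distance drone orthomosaics is typically
done with object-detection models that output bounding boxes with
confidence scores. Judging such maps needs more than the training-time AP
number: forest analysts want a thematic-map style confusion matrix with
true negatives, built over independently delineated reference polygons.
`crowneval` provides that evaluation machinery, plus the surrounding
stages, as a tested library and CLI:

- **geometry**: boxes, polygons, IoU, interior-overlap intersection
  predicates, disc buffers, grids;
- **synthetic scenes**: crown layouts at configured stem densities
  (3657 / 4744 / 8796 stems/ha block presets) with crown pixel areas from
  a truncated log-normal moment-matched to empirical statistics
  (mean 297.43 px, sd 203.53 px on [24, 1276] px), plus a stochastic
  detector surrogate and schematic imagery rendering;
- **chip export**: 256 px / 128 px-stride sliding-window tiling with 45°
  rotation orientations and PASCAL VOC XML annotations;
- **post-processing**: confidence thresholding (≥ 0.95 default) and
  greedy non-maximum suppression;
- **true negatives**: 1 m grid → center buffers (0.5 m / 1 m presets) →
  removal of crown-intersecting buffers → seeded subsampling to 500/400
  "Other" polygons;
- **assessment**: polygon-level TP/FP/FN/TN, precision / recall / overall
  accuracy, and IoU-matched average precision with all-points
  interpolation;
- **field plots**: fixed-area tally ingestion (0.3 m height rule) and
  density expansion (count × expansion factor × 2.471 acres/ha).

The core statistic is the polygon-level confusion matrix: a target
("White Pine") reference polygon intersecting at least one predicted box
is a TP, one intersecting none an FN; an "Other" polygon intersecting a
box is an FP, else a TN; then

    Precision = TP/(TP+FP)   Recall = TP/(TP+FN)   OA = (TP+TN)/(TP+FP+FN+TN)

See `docs/methods.md` for the full model description, parameter meanings,
and design rationale.

## Worked example

Build a deterministic 500-crown / 500-Other reference layout whose
detections hit exactly 412 crowns and 2 Other polygons, and evaluate it:

```python
from crowneval import (benchmark_layout, assign_outcomes,
                       compute_metrics, format_confusion_table)

crowns, others, dets = benchmark_layout(n_crowns=500, n_others=500,
                                        n_crowns_hit=412, n_others_hit=2)
cm = assign_outcomes(crowns, others, dets)
print(format_confusion_table(cm))
m = compute_metrics(cm)
print(f"precision={m.precision:.4f}  recall={m.recall:.4f}  OA={m.overall_accuracy:.4f}")
```

prints

```
Class       Detected  Not Detected  Total
White Pine  412 (TP)  88 (FN)       500
Other       2 (FP)    498 (TN)      500
Total       414       586           1000
precision=0.9952  recall=0.8240  OA=0.9100
```

Row totals equal the reference-layer sizes by construction — the unit of
assessment is the reference polygon, not the detection. Precision here
says 2 of 414 detection-positive polygons were non-target commission;
recall says 82.4 % of reference crowns were covered by at least one box;
OA is the fraction of all 1000 reference polygons classified correctly.

The same works end-to-end from a simulated scene via the CLI:

```bash
crowneval run-all --seed 7 --out run7          # full pipeline + report.json
crowneval simulate --extent 30 30 --density 4744 --seed 1 --out scene
crowneval tn-gen --crowns scene/crowns.geojson --extent 0 0 30 30 --n 200 --out others.geojson
crowneval postprocess --dets scene/detections.geojson --conf 0.95 --out dets.geojson
crowneval evaluate --crowns scene/crowns.geojson --others others.geojson --dets dets.geojson
```

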