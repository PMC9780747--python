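# Methods

## Problem and scope

A whole-testis cross-section scanned at x400 (nominally 0.161 um/px) shows
dozens to hundreds of seminiferous tubule cross-sections. Each belongs to
one of five pooled stages of the seminiferous epithelial cycle — I-V,
VI-VIII, IX, X-XI, XII — identifiable from its germ-cell association:
stages I-V and VI-VIII contain round spermatids (RS) plus bundled or
aligned late elongating spermatids; IX and X-XI lack RS and show early
elongating spermatids; XII is defined by meiotic figures (metaphase plates,
m2m, and/or secondary spermatocytes, Spc-sec). Cells are classified into 9
types: Sert, Spg, Spc-prePach, Spc-Pach, Spc-sec, m2m, RS, elSpt-early,
elSpt-late (annotation sources may split pachytene into early/late
subclasses, which are fused before any output).

This package implements everything around the detector: tiling and
stitching, ensemble merging, tubule assembly and stage voting, biological
consistency rules, antigen profiling, the metric suite, and a synthetic
generator. Training and shipping neural weights are out of scope; the
detector is a plug-in contract.

## Pipeline

1. **Tiling.** 1024x1024 tiles on a base lattice (step 1024) plus the same
   lattice shifted by (512, 512). Trailing partial tiles are dropped, not
   padded: padding would inject artificial dark tissue, and the shifted
   lattice recovers the overlap. Every pixel at distance >= 512 from the
   border is covered by >= 2 tiles. An optional foreground filter (mean
   fraction of pixels above an 8-bit intensity floor of 20; off by default)
   approximates the exclusion of empty-glass tiles when tiling real scans.
2. **Detection contract.** Backends return per-class confidence vectors.
   Score thresholds live in the contract, not the backends — cell
   detections below 0.5 and tubule fragments below 0.3 are suppressed
   identically for every backend — so backends stay comparable.
3. **Rotation ensemble (cells only).** Each tile is presented at all four
   quarter-turn rotations; detections are mapped back and merged greedily in
   descending confidence, discarding any detection whose IOU with a kept one
   is strictly above 0.5 (ties in confidence: lower rotation index wins, for
   determinism).
4. **Cross-tile merge.** In slide coordinates, detections cluster by single
   linkage at IOU >= 0.4. Cluster class scores are the summed member
   confidence vectors; the winner is the cluster label and the best
   positive runner-up is retained as the second-best label (used by the
   stage-XII rules). The merged box is the confidence-weighted mean of
   member boxes; the stored confidence vector is the vote sum divided by
   cluster size so it remains a sub-probability vector (the argmax and
   runner-up are unaffected). Single linkage was chosen because it is
   order-independent and simple; the merged-box rule is a configuration
   point, not a claim.
5. **Tubule assembly.** Fragments link when their pixel intersection is at
   least 0.1 of the smaller fragment's area; connected components become
   tubules (many-to-one). Ids are assigned by scanline order of union-mask
   centroids. The threshold is a design choice: touching-but-disjoint
   fragments do not merge.
6. **Stage vote.** Per fragment i and stage c the weight is
   `conf_i(c) * area_i / |union|`; the tubule score is the product over
   fragments, computed in log space with a floor of 1e-6 per factor so one
   zero-confidence fragment cannot veto a stage. Larger fragments therefore
   carry more weight. Ties break by stage order.
7. **Stage-XII rules.** Rule 1: a XII tubule containing no m2m/Spc-sec cell
   is restaged I-V. Rule 2: any m2m/Spc-sec cell in a non-XII tubule is
   relabeled to its second-best class if present, else deleted. The rules
   run once, in that order; Rule 2 does not re-trigger Rule 1 (a XII tubule
   emptied by Rule 2 would have had its meiotic figures *before* the rules,
   so the situation does not arise from Rule 1's precondition; the
   single-pass behavior is the documented choice for the remaining corner
   cases). Interstitial cells (box center inside no tubule mask) are
   outside the rules' scope. Cell-tubule assignment is by box center; on a
   shared boundary the lower tubule id wins.
8. **Curation.** Manual removal of artifactual tubules is replaced by an
   exclusion list of tubule ids (`--exclude-tubules`), applied after the
   rules and before reporting, plus the color overlay for visual review.

## Antigen profiling

The cell region is the axis-aligned ellipse inscribed in the cell's box
(pixel centers tested with <=; an oval around the nucleus). A cell is
positive for a marker when the region's mean raw luminosity is strictly
above the per-marker threshold T and at least 65% of region pixels exceed
T/2. T is user-set per marker, as in any immunofluorescence quantification;
a per-class intensity-histogram helper assists the choice but no automatic
threshold is claimed. Luminosity is measured on raw channel values, not
normalized ones. Profiles report positive/total counts and their ratio per
(cell class, stage); empty cells of the table are NaN, never silently zero.

## Metrics

Matching is greedy: predictions in descending confidence claim the
unclaimed truth with highest IOU >= 0.5. It is class-agnostic by default so
that classification quality can be scored afterwards (per-class PPV,
sensitivity, F1; confusion matrix over matched pairs); a class-aware
variant is available by flag. Ratios with empty denominators are reported
as undefined, and macro averages run over defined classes only. Average
precision follows the 101-point interpolation convention at a fixed IOU
threshold, averaged over classes with ground truth, reported on a 0-100
scale. Pixel metrics are the four classical semantic-segmentation numbers
(pixel accuracy, mean accuracy, mean IU, frequency-weighted IU) over stage
classes plus background, with means over classes present in the truth.
Staging agreement counts exact stage-class matches over a shared tubule id
set; an explicit override mapping reconciles borderline cross-sections
before counting (the package does not guess which side of a borderline
disagreement was "right"). Percentages are rounded to one decimal:
107/112 = 95.5%, 111/112 = 99.1%.

## Detector backends

**Oracle.** Emits generator ground truth with injectable noise: label flips
(to a uniformly random other class, with a documented confidence for
correct vs flipped emissions and the remainder spread uniformly), box
jitter, and drops. Noise is keyed on the cell's truth box, making a
simulated miss or mislabel intrinsic to the cell — consistent across the
rotation ensemble rather than voted away by it, so drop probability d costs
close to d of recall. Each cell is emitted exactly once, by the base-lattice
tile owning its box center, clipped to that tile: a cell can straddle a
base-lattice seam in one axis and a shifted-lattice seam in the other, in
which case no tile contains it whole, and emitting clipped partials in every
touching tile creates seam duplicates below the 0.4 merge threshold.
Tubule masks, by contrast, are clipped to every tile they touch — that is
what fragments tubules across the mosaic. Fragment stage labels are flipped
with the same probability as cell labels, so the degradation of stage
accuracy under label noise is exercised end to end.

**Baseline.** A weights-free classical detector for synthetic slides:
intensity threshold (floor 65), connected components, size filter
(12-3000 px), nearest-centroid classification in (area, mean intensity,
major/minor axis ratio) space against the renderer's documented class
centroids, confidence as a softmax over negative squared distances
(temperature 0.25 in normalized feature space). Its tubule segmentation is
a coarse smoothed-foreground pass with a near-uniform stage prior peaked on
the modal stage — it demonstrates detection plumbing, not staging.

## Synthetic generator

The generator renders what a chromatin stain shows structurally, not its
texture: elliptical tubules (radius 90-140 px, axis ratio 0.75-1.0) with a
bright peritubular ring, a dim epithelium, and a dark lumen, placed by
dart-throwing with a 14 px gap and a bounded attempt budget (an error is
raised if packing is infeasible). Stages are drawn per tubule from a mix
defaulting to {I-V: 0.40, VI-VIII: 0.25, IX: 0.10, X-XI: 0.15, XII: 0.10}
(early stages occupy most of the cycle; XII is rare). Cells are placed in
radial bands — Sertoli/spermatogonia basal, spermatocytes mid-epithelium,
spermatids luminal, late elongating spermatids angularly bundled in I-V —
with per-stage composition rules enforcing the stage definitions (XII
always receives at least one m2m or Spc-sec; IX-XII receive no RS in the
ideal generator, which omits transitional tubules). Nuclei are ellipses
with class-specific equivalent radius (3.5-12 px), mean 8-bit intensity
(80-250), and elongation (1.0-3.0, elongated nuclei pointing at the tubule
center), plus texture noise; the class signatures are pairwise separated in
(area, intensity, elongation) so the baseline detector is learnable.
Marker channels paint rule-positive nuclei at a configured contrast over a
dark background, giving exact positivity truth per marker. Knockout modes:
`miwi` removes all elongating spermatids from every stage's composition
(spermatogenic arrest at the round-spermatid step); `spef2` distorts
elongating-spermatid rendering (more elongated, rougher texture) while
keeping wild-type labels.

Two deliberate geometry choices are study conditions, stated once: tubule
radii are scaled down relative to real tissue (a real tubule is roughly
600 px across at 0.161 um/px) so that multi-tile slides stay small enough
for routine testing, and tissue keeps a 512 px border margin — real
cross-sections sit interior to the scanned frame, and only the interior
enjoys the two-lattice double coverage that makes exact zero-noise recovery
possible. Slides auto-size to multiples of 1024 px.

**What passing tests show — and do not.** With the zero-noise oracle the
pipeline recovers generator truth exactly (tubule count, stages, crosstab),
which validates the merging/voting/rule logic, not any detector. The
baseline detector's near-perfect accuracy on synthetic slides reflects the
generator's engineered class separability; real DAPI nuclei overlap in all
three features and require a trained model. Published performance numbers
of the reference neural models on real tissue are not reproducible here and
are used only as fixed inputs to verify metric arithmetic.

## Dataset bookkeeping

Tubule masks smaller than 12 000 px (about 1% of a tile) are removed from
training-style annotation sets (strictly smaller; 12 000 is kept).
Augmentation expands each input by an explicit variant list with labels
transformed consistently; two shipped presets reproduce the reference
dataset sizes — the 12-variant cell preset (4 rotations x {identity, blur,
brightness}: 424 images -> 5 088, 52 807 labels -> 633 684) and the
9-variant tubule preset (3 flips x {identity, blur, brightness}: 3 097
images -> 27 873). The reference datasets' differing factors (12 vs 9) are
not explained by their documentation; the presets are therefore explicit
lists, not a hard-coded rule.

## Numerical conventions

Coordinates are 0-based, x = column, y = row; boxes are half-open, so
integer box area is an exact pixel count, and all IOUs are computed on the
pixel lattice (box and mask IOU agree exactly on filled rectangles).
Rotations follow the CCW quarter-turn convention of `np.rot90` on a
[y, x]-indexed image. Ellipse boundary pixels are included when the pixel
center satisfies the inequality with <=. "Above the threshold" in the
positivity rule is strict >; "65% of pixels" is >= 0.65; both are
config-overridable. The product vote's 1e-6 floor, the 0.1 fragment-overlap
threshold, and all tie-breaks (rotation index, class order, stage order,
lower tubule id) are fixed for determinism: rerunning any pipeline with the
same seed and config is byte-identical.

## Known limitations

- Exactly one stage per tubule; transitional cross-sections (two stages in
  one tubule) are not modeled, mirroring the single-label output of the
  reference pipeline.
- The VIA importer handles rectangle (cell) and polygon (tubule) regions
  only.
- No pyramidal slide formats; TIFF/PNG single-channel input, with RGB
  reduced by BT.601 luma weights.
- Sub-pixel geometry, polygon-based continuous IOU, and multi-marker
  colocalization are out of scope.
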