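"""End-to-end whole-slide analysis driver.

Order of operations: slice the slide into the half-overlapping tile mosaic;
on each tile run the cell detector at all four 90-degree rotations and merge
the rotation ensemble; run the tubule segmenter once per tile; apply the
contract score thresholds; map everything to slide coordinates; merge
duplicate cell detections across tiles; fuse pachytene subclasses; group
tubule fragments into whole tubules; vote each tubule's stage; assign cells
to tubules; apply the stage-XII consistency rules; drop excluded tubules.
A structured log records object counts after every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import aggregation
from .aggregation import (
    apply_stage12_rules,
    assign_cells_to_tubules,
    group_fragments_to_tubules,
    merge_cross_tile,
    merge_rotation_ensemble,
    stage_all_tubules,
)
from .backends import (
    CELL_SCORE_MIN,
    TUBULE_SCORE_MIN,
    DetectorBackend,
    apply_score_thresholds,
    fuse_pachytene,
)
from .classes import CELL_CLASSES, STAGE_CLASSES
from .geometry import rotate_box
from .tiling import DEFAULT_SHIFT, DEFAULT_TILE_SIZE, slice_slide, to_slide_coords
from .types import CellDetection, SlideImage, Tubule

logger = logging.getLogger("tubulestage")


@dataclass(frozen=True)
class PipelineConfig:
    tile_size: int = DEFAULT_TILE_SIZE
    shift: int = DEFAULT_SHIFT
    cell_score_min: float = CELL_SCORE_MIN
    tubule_score_min: float = TUBULE_SCORE_MIN
    rotation_iou_max: float = aggregation.ROTATION_IOU_MAX
    cross_tile_iou_min: float = aggregation.CROSS_TILE_IOU_MIN
    fragment_overlap_min: float = aggregation.FRAGMENT_OVERLAP_MIN
    foreground_fraction_min: float = 0.0
    use_rotation_ensemble: bool = True
    #: tubule ids to drop from all reports (the exclusion-list replacement
    #: for manual curation of artifactual or longitudinal tubules)
    exclude_tubules: tuple[int, ...] = ()


@dataclass
class PipelineResult:
    cells: list[CellDetection]
    tubules: list[Tubule]
    assignment: list[Optional[int]]
    log: dict[str, int] = field(default_factory=dict)

    @property
    def interstitial(self) -> list[int]:
        return [i for i, a in enumerate(self.assignment) if a is None]

    def crosstab(self) -> pd.DataFrame:
        from .reports import crosstab_report

        return crosstab_report(self.cells, self.tubules, self.assignment)


def analyze_slide(
    slide: SlideImage,
    backend: DetectorBackend,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on one slide with the given detector backend."""
    cfg = config or PipelineConfig()
    counts: dict[str, int] = {}

    grid = slice_slide(
        slide,
        size=cfg.tile_size,
        shift=cfg.shift,
        foreground_fraction_min=cfg.foreground_fraction_min,
    )
    counts["tiles"] = len(grid)
    logger.info("sliced slide into %d tiles", len(grid))

    all_cells: list[CellDetection] = []
    all_fragments = []
    raw_cells = 0
    for tile in grid:
        rotations = range(4) if cfg.use_rotation_ensemble else (0,)
        per_rotation = []
        for k in rotations:
            dets = backend.detect_cells(tile.rotated(k))
            # map back from the rotated frame to the unrotated tile frame
            back = [
                CellDetection(
                    box=rotate_box(d.box, (4 - k) % 4, tile.size),
                    conf=d.conf,
                    top_class=d.top_class,
                    top_conf=d.top_conf,
                    second_class=d.second_class,
                    source=d.source or f"{tile.id}:r{k}",
                    n_merged=d.n_merged,
                )
                for d in dets
            ]
            per_rotation.append(back)
        raw_cells += sum(len(r) for r in per_rotation)
        tile_cells = merge_rotation_ensemble(per_rotation)
        fragments = backend.segment_tubules(tile)
        tile_cells, fragments = apply_score_thresholds(
            tile_cells, fragments, cfg.cell_score_min, cfg.tubule_score_min
        )
        all_cells.extend(to_slide_coords(c, tile) for c in tile_cells)
        all_fragments.extend(to_slide_coords(f, tile) for f in fragments)
    counts["raw_cell_detections"] = raw_cells
    counts["cells_after_rotation_merge"] = len(all_cells)
    counts["tubule_fragments"] = len(all_fragments)

    cells = merge_cross_tile(all_cells, iou_min=cfg.cross_tile_iou_min)
    counts["cells_after_cross_tile_merge"] = len(cells)
    cells = fuse_pachytene(cells)
    counts["cells_after_pachytene_fusion"] = len(cells)

    tubules = group_fragments_to_tubules(
        all_fragments, overlap_min=cfg.fragment_overlap_min
    )
    counts["tubules"] = len(tubules)
    stage_all_tubules(tubules)
    assignment = assign_cells_to_tubules(cells, tubules)
    cells, assignment = apply_stage12_rules(tubules, cells, assignment)
    counts["cells_after_stage12_rules"] = len(cells)

    if cfg.exclude_tubules:
        excluded = set(cfg.exclude_tubules)
        tubules = [t for t in tubules if t.id not in excluded]
        keep = [
            (c, a) for c, a in zip(cells, assignment)
            if a is None or a not in excluded
        ]
        cells = [c for c, _ in keep]
        assignment = [a for _, a in keep]
        for tub in tubules:
            tub.cells = [i for i, a in enumerate(assignment) if a == tub.id]
    counts["tubules_reported"] = len(tubules)
    counts["cells_reported"] = len(cells)

    for step, value in counts.items():
        logger.info("pipeline count %-32s %d", step, value)
    return PipelineResult(cells=cells, tubules=tubules, assignment=assignment, log=counts)


def stage_accuracy(result: PipelineResult, truth_ann) -> float:
    """Fraction of predicted tubules whose voted stage matches the stage of
    the ground-truth tubule their union mask overlaps most."""
    if not result.tubules:
        raise ValueError("no tubules in result")
    correct = 0
    for tub in result.tubules:
        best, best_inter = None, 0
        for t in truth_ann.tubules:
            inter = tub.union_mask.intersection_area(t.mask)
            if inter > best_inter:
                best, best_inter = t, inter
        if best is not None and best.stage == tub.stage:
            correct += 1
    return correct / len(result.tubules)
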