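"""Prediction merging, tubule assembly, stage voting, and consistency rules.

This module implements the decision logic that turns per-tile, per-rotation
raw predictions into a whole-slide result:

* rotation-ensemble merging of cell detections (greedy NMS, IOU strictly
  greater than 0.5 discards);
* cross-tile merging of duplicate detections from the half-overlapping
  mosaic (single-linkage clusters at IOU >= 0.4, weighted majority vote over
  summed per-class confidences, second-best label retained);
* many-to-one grouping of tubule mask fragments into whole tubules;
* area-weighted product voting for the tubule stage;
* the two stage-XII consistency rules tying the tubule model to the cell
  model (a stage-XII call requires meiotic figures; meiotic figures outside
  stage XII are demoted or deleted).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .classes import (
    CELL_CLASS_INDEX,
    STAGE_CLASS_INDEX,
    STAGE_CLASSES,
    STAGE_XII_MARKER_CLASSES,
)
from .geometry import BoundingBox, box_iou
from .types import CellDetection, Tubule, TubuleFragment

ROTATION_IOU_MAX = 0.5      # strict >: equal-to-threshold pairs are both kept
CROSS_TILE_IOU_MIN = 0.4    # inclusive >=
FRAGMENT_OVERLAP_MIN = 0.1  # fraction of the smaller fragment's area
VOTE_FLOOR = 1e-6           # keeps one zero-confidence fragment from vetoing


def _source_rotation(det: CellDetection) -> int:
    # provenance strings end in ":r<k>"; unknown provenance sorts last
    src = det.source
    if ":r" in src:
        try:
            return int(src.rsplit(":r", 1)[1])
        except ValueError:
            pass
    return 9


def merge_rotation_ensemble(
    per_rotation: Sequence[Sequence[CellDetection]],
) -> list[CellDetection]:
    """Merge the four per-rotation detection lists for one tile.

    All inputs must already be mapped back to the unrotated tile frame.
    Detections are sorted by descending confidence (ties: lower rotation
    index, then canonical class order) and kept greedily if their IOU with
    every already-kept detection is <= 0.5; overlap strictly above 0.5
    discards the lower-ranked duplicate.
    """
    pool = [d for rot in per_rotation for d in rot]
    pool.sort(
        key=lambda d: (
            -d.top_conf,
            _source_rotation(d),
            CELL_CLASS_INDEX.get(d.top_class, 99),
            d.box.x0,
            d.box.y0,
        )
    )
    kept: list[CellDetection] = []
    for det in pool:
        if all(box_iou(det.box, k.box) <= ROTATION_IOU_MAX for k in kept):
            kept.append(det)
    return kept


# ---------------------------------------------------------------------------
# cross-tile merge
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _pairwise_box_iou(boxes: np.ndarray) -> np.ndarray:
    x0 = np.maximum(boxes[:, None, 0], boxes[None, :, 0])
    y0 = np.maximum(boxes[:, None, 1], boxes[None, :, 1])
    x1 = np.minimum(boxes[:, None, 2], boxes[None, :, 2])
    y1 = np.minimum(boxes[:, None, 3], boxes[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    union = areas[:, None] + areas[None, :] - inter
    return inter / union


def merge_cross_tile(
    cells: Sequence[CellDetection], iou_min: float = CROSS_TILE_IOU_MIN
) -> list[CellDetection]:
    """Fuse duplicate detections of the same cell from overlapping tiles.

    Detections are clustered by single linkage at IOU >= ``iou_min``. Each
    cluster votes: per-class score = sum of member confidence vectors; the
    top class wins and the runner-up (if any class other than the winner has
    positive score) is retained as the second-best label. The merged box is
    the confidence-weighted mean of member boxes, and the stored confidence
    vector is the vote sum divided by cluster size so it remains a
    (sub-)probability vector. Idempotent on well-separated output.
    """
    if not cells:
        return []
    boxes = np.array([c.box.as_tuple() for c in cells], dtype=float)
    iou = _pairwise_box_iou(boxes)
    uf = _UnionFind(len(cells))
    ii, jj = np.nonzero(iou >= iou_min)
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i < j:
            uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(cells)):
        clusters.setdefault(uf.find(i), []).append(i)

    merged: list[CellDetection] = []
    for members in clusters.values():
        dets = [cells[i] for i in members]
        score: dict[str, float] = {}
        for d in dets:
            for cls, val in d.conf.items():
                score[cls] = score.get(cls, 0.0) + val
        order = sorted(
            score.items(), key=lambda kv: (-kv[1], CELL_CLASS_INDEX.get(kv[0], 99))
        )
        top_class = order[0][0]
        second = next((cls for cls, val in order[1:] if val > 0.0), None)
        weights = np.array([d.top_conf for d in dets])
        weights = weights / weights.sum()
        mb = (np.array([d.box.as_tuple() for d in dets]) * weights[:, None]).sum(axis=0)
        n_members = sum(d.n_merged for d in dets)
        conf = {cls: val / len(dets) for cls, val in score.items()}
        top_conf = max(conf.values())
        merged.append(
            CellDetection(
                box=BoundingBox(*mb.tolist()),
                conf=conf,
                top_class=top_class,
                top_conf=top_conf,
                second_class=second,
                source=dets[0].source,
                n_merged=n_members,
            )
        )
    merged.sort(key=lambda d: (d.box.y0, d.box.x0, d.box.y1, d.box.x1))
    return merged


# ---------------------------------------------------------------------------
# tubule assembly and staging
# ---------------------------------------------------------------------------

def group_fragments_to_tubules(
    fragments: Sequence[TubuleFragment],
    overlap_min: float = FRAGMENT_OVERLAP_MIN,
) -> list[Tubule]:
    """Many-to-one mapping of predicted masks to whole tubules.

    Two fragments are linked when their pixel intersection is at least
    ``overlap_min`` times the smaller fragment's area; connected components
    of that graph become tubules. Ids are assigned in scanline order of the
    union-mask centroids, making them deterministic.
    """
    n = len(fragments)
    uf = _UnionFind(n)
    # bbox prefilter keeps the pairwise pass cheap
    bbs = [f.mask.bbox for f in fragments]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = bbs[i], bbs[j]
            if a.x1 <= b.x0 or b.x1 <= a.x0 or a.y1 <= b.y0 or b.y1 <= a.y0:
                continue
            inter = fragments[i].mask.intersection_area(fragments[j].mask)
            smaller = min(fragments[i].area_px, fragments[j].area_px)
            if smaller > 0 and inter >= overlap_min * smaller:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    assembled = []
    for members in groups.values():
        frags = [fragments[i] for i in members]
        union = frags[0].mask
        for f in frags[1:]:
            union = union.union(f.mask)
        assembled.append((union, frags))
    assembled.sort(key=lambda t: (round(t[0].centroid()[1]), round(t[0].centroid()[0])))
    return [
        Tubule(id=i, union_mask=union, fragments=frags)
        for i, (union, frags) in enumerate(assembled)
    ]


def vote_tubule_stage(tubule: Tubule) -> tuple[str, dict[str, float]]:
    """Area-weighted product vote over fragment stage confidences.

    For fragment ``i`` and stage ``c`` the weight is
    ``stage_conf_i(c) * area_i / union_area``; the tubule score is the
    product over fragments, computed in log space with a 1e-6 floor per
    factor so a single zero-confidence fragment cannot veto a stage. Ties
    break by stage-class order.
    """
    if not tubule.fragments:
        raise ValueError(f"tubule {tubule.id} has no fragments")
    union_area = float(tubule.union_mask.area)
    log_score = {s: 0.0 for s in STAGE_CLASSES}
    for frag in tubule.fragments:
        frac = frag.area_px / union_area
        for s in STAGE_CLASSES:
            w = frag.stage_conf.get(s, 0.0) * frac
            log_score[s] += math.log(max(w, VOTE_FLOOR))
    stage = min(log_score, key=lambda s: (-log_score[s], STAGE_CLASS_INDEX[s]))
    return stage, {s: math.exp(v) for s, v in log_score.items()}


def stage_all_tubules(tubules: Sequence[Tubule]) -> None:
    for tub in tubules:
        tub.stage, tub.stage_score = vote_tubule_stage(tub)


def assign_cells_to_tubules(
    cells: Sequence[CellDetection], tubules: Sequence[Tubule]
) -> list[Optional[int]]:
    """Tubule id containing each cell's box center; None marks interstitial
    cells. If union masks overlap on a boundary pixel the lower tubule id
    wins."""
    assignment: list[Optional[int]] = []
    ordered = sorted(tubules, key=lambda t: t.id)
    for cell in cells:
        cx, cy = cell.box.center
        hit = next(
            (t.id for t in ordered if t.union_mask.contains_point(cx, cy)), None
        )
        assignment.append(hit)
    for tub in tubules:
        tub.cells = [i for i, a in enumerate(assignment) if a == tub.id]
    return assignment


def apply_stage12_rules(
    tubules: Sequence[Tubule],
    cells: Sequence[CellDetection],
    assignment: Sequence[Optional[int]],
) -> tuple[list[CellDetection], list[Optional[int]]]:
    """Biological consistency between tubule staging and meiotic figures.

    Rule 1 (then) Rule 2, each applied once:

    1. A tubule staged XII containing no cell labeled m2m or Spc-sec is
       restaged I-V (a stage-XII call requires visible meiotic figures).
    2. Any m2m / Spc-sec cell sitting in a tubule *not* staged XII is
       relabeled to its second-best class if one was retained, otherwise
       deleted. Interstitial meiotic figures are left untouched.

    Rule 2 does not re-trigger Rule 1. Returns the updated cell list and
    assignment (entries for deleted cells removed); tubule stages and member
    lists are updated in place.
    """
    by_id = {t.id: t for t in tubules}
    for tub in tubules:
        if tub.stage != "XII":
            continue
        members = [cells[i] for i, a in enumerate(assignment) if a == tub.id]
        if not any(c.top_class in STAGE_XII_MARKER_CLASSES for c in members):
            tub.stage = "I-V"

    new_cells: list[CellDetection] = []
    new_assignment: list[Optional[int]] = []
    for cell, tub_id in zip(cells, assignment):
        if (
            cell.top_class in STAGE_XII_MARKER_CLASSES
            and tub_id is not None
            and by_id[tub_id].stage != "XII"
        ):
            if cell.second_class is not None:
                new_cells.append(cell.relabeled(cell.second_class))
                new_assignment.append(tub_id)
            # no second-best prediction: delete the cell
            continue
        new_cells.append(cell)
        new_assignment.append(tub_id)
    for tub in tubules:
        tub.cells = [i for i, a in enumerate(new_assignment) if a == tub.id]
    return new_cells, new_assignment


def check_stage12_invariant(
    tubules: Sequence[Tubule],
    cells: Sequence[CellDetection],
    assignment: Sequence[Optional[int]],
) -> bool:
    """Global postcondition of the rules: no meiotic-figure label outside a
    XII tubule, and every XII tubule contains at least one."""
    by_id = {t.id: t for t in tubules}
    for cell, tub_id in zip(cells, assignment):
        if cell.top_class in STAGE_XII_MARKER_CLASSES:
            if tub_id is None:
                continue  # interstitial cells are outside the rules' scope
            if by_id[tub_id].stage != "XII":
                return False
    for tub in tubules:
        if tub.stage == "XII":
            members = [cells[i] for i, a in enumerate(assignment) if a == tub.id]
            if not any(c.top_class in STAGE_XII_MARKER_CLASSES for c in members):
                return False
    return True
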