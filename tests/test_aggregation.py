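"""Merging, tubule assembly, stage voting, and the stage-XII rules."""

import numpy as np
import pytest

from tubulestage.aggregation import (
    apply_stage12_rules,
    assign_cells_to_tubules,
    check_stage12_invariant,
    group_fragments_to_tubules,
    merge_cross_tile,
    merge_rotation_ensemble,
    stage_all_tubules,
    vote_tubule_stage,
)
from tubulestage.classes import STAGE_CLASSES
from tubulestage.geometry import BoundingBox, PixelMask, box_iou
from tubulestage.types import CellDetection, Tubule, TubuleFragment


def _det(box, cls, conf, source="t0_0:r0", second=None):
    vec = {cls: conf}
    det = CellDetection.from_conf(BoundingBox(*box), vec, source=source)
    if second is not None:
        det = CellDetection(box=det.box, conf=det.conf, top_class=det.top_class,
                            top_conf=det.top_conf, second_class=second, source=source)
    return det


def _frag(x0, y0, w, h, stage_conf):
    return TubuleFragment(mask=PixelMask(x0, y0, np.ones((h, w), dtype=bool)),
                          stage_conf=stage_conf)


class TestRotationEnsemble:
    def test_single_populated_rotation_passes_through(self):
        dets = [_det((0, 0, 10, 10), "RS", 0.9)]
        assert merge_rotation_ensemble([dets, [], [], []]) == dets

    def test_identical_box_keeps_highest_confidence(self):
        a = _det((0, 0, 10, 10), "RS", 0.9, source="t0_0:r0")
        b = _det((0, 0, 10, 10), "RS", 0.8, source="t0_0:r1")
        merged = merge_rotation_ensemble([[a], [b], [], []])
        assert merged == [a]

    def test_threshold_is_strictly_greater_than_half(self):
        """Two boxes at IOU exactly 0.5 and below it are both kept; only
        overlap strictly above 0.5 discards."""
        a = _det((0, 0, 10, 10), "RS", 0.9)
        b_at_half = _det((0, 5, 10, 15), "RS", 0.8)       # IOU = 50/150 ... build exact 0.5
        # boxes (0,0,10,10) and (0,2,10,12): inter 80, union 120 -> 2/3 > 0.5
        c_above = _det((0, 2, 10, 12), "RS", 0.8)
        # (0,0,10,10) vs (0,5,10,15): inter 50 union 150 -> 1/3 kept
        assert box_iou(a.box, b_at_half.box) == pytest.approx(1 / 3)
        kept = merge_rotation_ensemble([[a], [b_at_half], [c_above], []])
        assert a in kept and b_at_half in kept and c_above not in kept

    def test_iou_exactly_half_keeps_both(self):
        a = _det((0, 0, 10, 10), "RS", 0.9)
        # (0,0,10,10) vs (0,0,10,20)? inter 100, union 200 -> exactly 0.5
        b = _det((0, 0, 10, 20), "Sert", 0.8)
        assert box_iou(a.box, b.box) == 0.5
        kept = merge_rotation_ensemble([[a], [b], [], []])
        assert len(kept) == 2

    def test_confidence_tie_keeps_lower_rotation_index(self):
        a = _det((0, 0, 10, 10), "RS", 0.9, source="t0_0:r2")
        b = _det((1, 0, 11, 10), "Sert", 0.9, source="t0_0:r1")
        assert box_iou(a.box, b.box) > 0.5
        kept = merge_rotation_ensemble([[], [b], [a], []])
        assert kept == [b]


class TestCrossTileMerge:
    def test_singleton_cluster_unchanged_with_no_second_class(self):
        d = _det((0, 0, 10, 10), "RS", 1.0)
        merged = merge_cross_tile([d])
        assert len(merged) == 1
        assert merged[0].top_class == "RS" and merged[0].second_class is None

    def test_two_member_vote_keeps_stronger_class_and_runner_up(self):
        a = _det((0, 0, 10, 10), "RS", 0.9)
        b = _det((0, 0, 10, 10), "Spc-Pach", 0.6)
        (m,) = merge_cross_tile([a, b])
        assert m.top_class == "RS" and m.second_class == "Spc-Pach"
        assert m.n_merged == 2

    def test_summed_votes_beat_single_higher_confidence(self):
        dets = [
            _det((0, 0, 10, 10), "RS", 0.5),
            _det((0, 0, 10, 10), "Spc-Pach", 0.4),
            _det((0, 0, 10, 10), "Spc-Pach", 0.3),
        ]
        (m,) = merge_cross_tile(dets)
        assert m.top_class == "Spc-Pach" and m.second_class == "RS"

    def test_iou_threshold_inclusive_at_0_4(self):
        a = _det((0, 0, 10, 10), "RS", 0.9)
        # (0,0,10,10) vs (0,3,10,13): inter 70, union 130 -> 0.538 >= 0.4 merge
        b = _det((0, 3, 10, 13), "RS", 0.8)
        merged = merge_cross_tile([a, b])
        assert len(merged) == 1
        # far apart: no merge
        c = _det((50, 50, 60, 60), "RS", 0.8)
        assert len(merge_cross_tile([a, c])) == 2

    def test_idempotent(self, oracle_result):
        once = oracle_result.cells
        twice = merge_cross_tile(once)
        assert len(twice) == len(once)
        assert all(a.top_class == b.top_class and a.box == b.box
                   for a, b in zip(once, twice))


class TestFragmentGrouping:
    def test_single_and_disjoint_fragments(self):
        u = {s: 1.0 / 5 for s in STAGE_CLASSES}
        one = group_fragments_to_tubules([_frag(0, 0, 20, 20, u)])
        assert len(one) == 1 and one[0].union_mask.area == 400
        two = group_fragments_to_tubules([_frag(0, 0, 20, 20, u), _frag(100, 100, 20, 20, u)])
        assert len(two) == 2

    def test_transitive_chain_forms_one_tubule(self):
        """A overlaps B, B overlaps C, A and C disjoint: connected components
        still bind all three into one tubule."""
        u = {s: 1.0 / 5 for s in STAGE_CLASSES}
        a = _frag(0, 0, 20, 20, u)
        b = _frag(15, 0, 20, 20, u)
        c = _frag(30, 0, 20, 20, u)
        assert a.mask.intersection_area(c.mask) == 0
        tubs = group_fragments_to_tubules([a, b, c])
        assert len(tubs) == 1 and len(tubs[0].fragments) == 3

    def test_overlap_below_threshold_stays_separate(self):
        u = {s: 1.0 / 5 for s in STAGE_CLASSES}
        a = _frag(0, 0, 20, 20, u)          # area 400
        b = _frag(19, 0, 20, 20, u)         # overlap 20 px = 5% of smaller
        tubs = group_fragments_to_tubules([a, b], overlap_min=0.1)
        assert len(tubs) == 2


class TestStageVote:
    def test_single_fragment_takes_its_best_stage(self):
        conf = {"I-V": 0.9, "VI-VIII": 0.05, "IX": 0.02, "X-XI": 0.02, "XII": 0.01}
        tub = Tubule(0, _frag(0, 0, 10, 10, conf).mask, [_frag(0, 0, 10, 10, conf)])
        stage, _ = vote_tubule_stage(tub)
        assert stage == "I-V"

    def test_area_weighted_product_arithmetic(self):
        """75%-area fragment at 0.8 for I-V beats 25%-area fragment at 0.7
        for VI-VIII: S(I-V)=0.045 > S(VI-VIII)=0.02625."""
        a = _frag(0, 0, 75, 1, {"I-V": 0.8, "VI-VIII": 0.2})
        b = _frag(75, 0, 25, 1, {"I-V": 0.3, "VI-VIII": 0.7})
        tub = Tubule(0, a.mask.union(b.mask), [a, b])
        stage, score = vote_tubule_stage(tub)
        assert stage == "I-V"
        assert score["I-V"] == pytest.approx(0.6 * 0.075, rel=1e-9)
        assert score["VI-VIII"] == pytest.approx(0.15 * 0.175, rel=1e-9)

    def test_unanimous_fragments_win_regardless_of_areas(self, rng):
        frags = [
            _frag(i * 10, 0, 10, int(rng.integers(1, 30)), {"IX": 0.8, "I-V": 0.1})
            for i in range(5)
        ]
        union = frags[0].mask
        for f in frags[1:]:
            union = union.union(f.mask)
        stage, _ = vote_tubule_stage(Tubule(0, union, frags))
        assert stage == "IX"

    def test_log_space_equals_direct_product(self, rng):
        """Log-space accumulation must match the naive floored product to
        1e-9 relative tolerance on random fixtures."""
        for _ in range(50):
            n = int(rng.integers(1, 8))
            frags = [
                _frag(i * 12, 0, 12, int(rng.integers(1, 20)),
                      {s: float(rng.uniform(0, 1)) for s in STAGE_CLASSES})
                for i in range(n)
            ]
            union = frags[0].mask
            for f in frags[1:]:
                union = union.union(f.mask)
            tub = Tubule(0, union, frags)
            _, score = vote_tubule_stage(tub)
            for s in STAGE_CLASSES:
                direct = 1.0
                for f in frags:
                    direct *= max(f.stage_conf[s] * f.area_px / union.area, 1e-6)
                assert score[s] == pytest.approx(direct, rel=1e-9)

    def test_empty_fragment_list_rejected(self):
        tub = Tubule(0, PixelMask(0, 0, np.ones((2, 2), dtype=bool)), [])
        with pytest.raises(ValueError):
            vote_tubule_stage(tub)


class TestCellAssignment:
    def _tubules(self):
        u = {s: 1.0 / 5 for s in STAGE_CLASSES}
        a = _frag(0, 0, 50, 50, u)
        b = _frag(50, 0, 50, 50, u)   # adjacent, shares boundary column x=50
        tubs = group_fragments_to_tubules([a, b])
        return tubs

    def test_inside_outside_and_boundary_tiebreak(self):
        tubs = self._tubules()
        inside = _det((10, 10, 20, 20), "RS", 1.0)
        outside = _det((200, 200, 210, 210), "RS", 1.0)
        assignment = assign_cells_to_tubules([inside, outside], tubs)
        assert assignment[0] == 0 and assignment[1] is None

    def test_overlapping_masks_lower_id_wins(self):
        u = {s: 1.0 / 5 for s in STAGE_CLASSES}
        # two fully identical masks forced into separate tubules via threshold 1.1
        a = Tubule(0, _frag(0, 0, 30, 30, u).mask, [_frag(0, 0, 30, 30, u)])
        b = Tubule(1, _frag(0, 0, 30, 30, u).mask, [_frag(0, 0, 30, 30, u)])
        det = _det((10, 10, 20, 20), "RS", 1.0)
        assert assign_cells_to_tubules([det], [a, b]) == [0]


class TestStage12Rules:
    def _tubule(self, tid, stage, x0=0):
        u = {stage: 1.0}
        frag = _frag(x0, 0, 40, 40, {s: (1.0 if s == stage else 0.0) for s in STAGE_CLASSES})
        tub = Tubule(tid, frag.mask, [frag])
        tub.stage = stage
        return tub

    def test_xii_with_metaphase_plate_unchanged(self):
        tub = self._tubule(0, "XII")
        cells = [_det((10, 10, 20, 20), "m2m", 1.0)]
        assignment = assign_cells_to_tubules(cells, [tub])
        new_cells, new_assignment = apply_stage12_rules([tub], cells, assignment)
        assert tub.stage == "XII" and new_cells == cells
        assert check_stage12_invariant([tub], new_cells, new_assignment)

    def test_xii_without_meiotic_figures_restaged_to_early(self):
        tub = self._tubule(0, "XII")
        cells = [_det((10, 10, 20, 20), "RS", 1.0)]
        assignment = assign_cells_to_tubules(cells, [tub])
        apply_stage12_rules([tub], cells, assignment)
        assert tub.stage == "I-V"

    def test_meiotic_cell_outside_xii_demoted_or_deleted(self):
        tub = self._tubule(0, "I-V")
        with_second = _det((5, 5, 15, 15), "Spc-sec", 0.8, second="RS")
        without_second = _det((25, 25, 35, 35), "m2m", 0.8)
        cells = [with_second, without_second]
        assignment = assign_cells_to_tubules(cells, [tub])
        new_cells, new_assignment = apply_stage12_rules([tub], cells, assignment)
        assert len(new_cells) == 1
        assert new_cells[0].top_class == "RS"
        assert check_stage12_invariant([tub], new_cells, new_assignment)

    def test_interstitial_meiotic_cells_untouched(self):
        tub = self._tubule(0, "I-V")
        stray = _det((200, 200, 210, 210), "m2m", 0.9)
        cells = [stray]
        assignment = assign_cells_to_tubules(cells, [tub])
        new_cells, _ = apply_stage12_rules([tub], cells, assignment)
        assert new_cells == [stray]
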