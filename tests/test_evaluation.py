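"""Detection/segmentation metrics and staging agreement."""

import numpy as np
import pytest

from tubulestage.evaluation import (
    GroundTruthBox,
    average_precision,
    confusion_matrix,
    detection_prf,
    f1_score,
    macro_average,
    match_detections,
    pixel_metrics,
    staging_agreement,
)
from tubulestage.geometry import BoundingBox, box_iou
from tubulestage.types import CellDetection

# Published per-class detection quality of the reference neural cell model,
# used as fixed inputs to verify the metric arithmetic.
REFERENCE_PRF_TABLE = {
    "Sert": (0.9934, 0.9700, 0.9815),
    "Spg": (0.9152, 0.7593, 0.8300),
    "Spc-prePach": (0.9390, 0.8964, 0.9173),
    "Spc-Pach": (0.9782, 0.9352, 0.9562),
    "Spc-sec": (0.9906, 0.8203, 0.8974),
    "m2m": (0.9500, 0.8261, 0.8837),
    "RS": (0.9947, 0.9033, 0.9468),
    "elSpt-early": (0.9243, 0.7680, 0.8389),
    "elSpt-late": (0.9611, 0.6829, 0.7985),
}


def _det(box, cls, conf):
    return CellDetection.from_conf(BoundingBox(*box), {cls: conf})


class TestMatching:
    def test_identical_sets_fully_matched(self):
        truth = [GroundTruthBox(BoundingBox(i * 20, 0, i * 20 + 10, 10), "RS") for i in range(5)]
        pred = [_det(t.box.as_tuple(), "RS", 0.9) for t in truth]
        m = match_detections(pred, truth)
        assert len(m.pairs) == 5 and not m.false_positives and not m.false_negatives

    def test_empty_predictions_all_truths_unmatched(self):
        truth = [GroundTruthBox(BoundingBox(0, 0, 10, 10), "RS")]
        m = match_detections([], truth)
        assert m.false_negatives == truth

    def test_higher_confidence_claims_shared_truth(self):
        truth = [GroundTruthBox(BoundingBox(0, 0, 10, 10), "RS")]
        strong = _det((0, 0, 10, 10), "RS", 0.9)
        weak = _det((1, 0, 11, 10), "RS", 0.7)
        m = match_detections([weak, strong], truth)
        assert m.pairs == [(strong, truth[0])]
        assert m.false_positives == [weak]

    def test_conservation(self, rng):
        """TP+FP = predictions and TP+FN = truths on random fixtures."""
        for _ in range(20):
            truth = [
                GroundTruthBox(BoundingBox(x, y, x + 10, y + 10), "RS")
                for x, y in rng.integers(0, 200, size=(15, 2))
            ]
            pred = [
                _det((x, y, x + 10, y + 10), "RS", float(rng.uniform(0.5, 1)))
                for x, y in rng.integers(0, 200, size=(12, 2))
            ]
            m = match_detections(pred, truth)
            assert len(m.pairs) + len(m.false_positives) == len(pred)
            assert len(m.pairs) + len(m.false_negatives) == len(truth)


class TestPrfArithmetic:
    def test_perfect_labels_give_ones(self):
        truth = [GroundTruthBox(BoundingBox(i * 20, 0, i * 20 + 10, 10), "RS") for i in range(4)]
        pred = [_det(t.box.as_tuple(), "RS", 1.0) for t in truth]
        prf = detection_prf(match_detections(pred, truth))
        assert prf["RS"].ppv == prf["RS"].sensitivity == prf["RS"].f1 == 1.0

    def test_undefined_reported_as_none_not_zero(self):
        truth = [GroundTruthBox(BoundingBox(0, 0, 10, 10), "RS")]
        prf = detection_prf(match_detections([], truth))
        assert prf["Sert"].ppv is None and prf["Sert"].sensitivity is None
        assert prf["RS"].sensitivity == 0.0 and prf["RS"].ppv is None

    @pytest.mark.parametrize("cls", ["Sert", "Spg", "RS", "elSpt-late"])
    def test_f1_reproduces_reference_values(self, cls):
        """The harmonic mean of the tabulated PPV/sensitivity reproduces the
        tabulated F1. Inputs are 4-decimal roundings of the original values,
        which can move the recomputed F1 by up to ~1e-4 in the last digit
        (Sert: 0.98156 vs the tabulated 0.9815), hence the tolerance."""
        ppv, sens, f1 = REFERENCE_PRF_TABLE[cls]
        assert f1_score(ppv, sens) == pytest.approx(f1, abs=1.5e-4)

    def test_macro_averages_reproduce_reference_values(self):
        ppvs = {c: v[0] for c, v in REFERENCE_PRF_TABLE.items()}
        sens = {c: v[1] for c, v in REFERENCE_PRF_TABLE.items()}
        assert macro_average(ppvs) == pytest.approx(0.9607, abs=5e-5)
        assert macro_average(sens) == pytest.approx(0.8402, abs=5e-5)

    def test_macro_average_edge_cases(self):
        assert macro_average({"a": 0.5, "b": 0.5, "c": None}) == 0.5
        with pytest.raises(ValueError):
            macro_average({"a": None})


class TestConfusionMatrix:
    def test_perfect_labels_diagonal(self):
        truth = [GroundTruthBox(BoundingBox(i * 20, 0, i * 20 + 10, 10), "Spg") for i in range(3)]
        pred = [_det(t.box.as_tuple(), "Spg", 1.0) for t in truth]
        mat = confusion_matrix(match_detections(pred, truth))
        assert mat.loc["Spg", "Spg"] == 3 and mat.values.sum() == 3

    def test_single_mislabeled_pair_off_diagonal(self):
        truth = [GroundTruthBox(BoundingBox(0, 0, 10, 10), "Spg")]
        pred = [_det((0, 0, 10, 10), "Spc-prePach", 1.0)]
        mat = confusion_matrix(match_detections(pred, truth))
        assert mat.loc["Spg", "Spc-prePach"] == 1 and mat.values.sum() == 1

    def test_trace_equals_prf_true_positives(self, rng):
        classes = ["RS", "Spg", "Sert"]
        truth, pred = [], []
        for i in range(30):
            x, y = rng.integers(0, 400, 2).tolist()
            cls = classes[int(rng.integers(3))]
            truth.append(GroundTruthBox(BoundingBox(x, y, x + 10, y + 10), cls))
            pred.append(_det((x, y, x + 10, y + 10), classes[int(rng.integers(3))],
                             float(rng.uniform(0.5, 1))))
        m = match_detections(pred, truth)
        mat = confusion_matrix(m)
        prf = detection_prf(m)
        assert np.trace(mat.values) == sum(v.tp for v in prf.values())
        # row sums equal matched-truth counts per class
        for c in classes:
            assert mat.loc[c].sum() == sum(1 for _, t in m.pairs if t.cls == c)


class TestAveragePrecision:
    def test_perfect_predictions_give_100(self):
        truth = [GroundTruthBox(BoundingBox(i * 20, 0, i * 20 + 10, 10), "RS") for i in range(4)]
        pred = [_det(t.box.as_tuple(), "RS", 0.9) for t in truth]
        assert average_precision(pred, truth) == pytest.approx(100.0)

    def test_no_predictions_give_0(self):
        truth = [GroundTruthBox(BoundingBox(0, 0, 10, 10), "RS")]
        assert average_precision([], truth) == 0.0

    def test_three_prediction_two_truth_hand_computed_curve(self):
        """Ranking TP(0.9), FP(0.8), TP(0.7) over 2 truths: precision envelope
        is 1 up to recall 0.5 then 2/3, so the 101-point AP is
        (51*1 + 50*2/3)/101."""
        truth = [
            GroundTruthBox(BoundingBox(0, 0, 10, 10), "RS"),
            GroundTruthBox(BoundingBox(20, 0, 30, 10), "RS"),
        ]
        pred = [
            _det((0, 0, 10, 10), "RS", 0.9),
            _det((40, 0, 50, 10), "RS", 0.8),
            _det((20, 0, 30, 10), "RS", 0.7),
        ]
        expect = 100 * (51 * 1.0 + 50 * (2 / 3)) / 101
        assert average_precision(pred, truth) == pytest.approx(expect, abs=1e-9)

    def test_ap_monotone_in_iou_threshold(self, rng):
        truth, pred = [], []
        for x, y in rng.integers(0, 300, size=(20, 2)):
            truth.append(GroundTruthBox(BoundingBox(int(x), int(y), int(x) + 12, int(y) + 12), "RS"))
            jx, jy = rng.integers(0, 4, 2).tolist()
            pred.append(_det((int(x) + jx, int(y) + jy, int(x) + 12 + jx, int(y) + 12 + jy),
                             "RS", float(rng.uniform(0.5, 1))))
        assert average_precision(pred, truth, 0.5) >= average_precision(pred, truth, 0.75)

    def test_matches_brute_force_enumeration(self, rng):
        """AP must agree with an independent brute-force PR computation
        (precision maxima over explicit prediction prefixes) on 200 random
        small fixtures."""
        for _ in range(200):
            n_truth = int(rng.integers(1, 5))
            n_pred = int(rng.integers(0, 6))
            truth = [
                GroundTruthBox(BoundingBox(int(x), 0, int(x) + 10, 10), "RS")
                for x in rng.integers(0, 8, n_truth) * 20
            ]
            pred = [
                _det((int(x * 20 + d), 0, int(x * 20 + d) + 10, 10), "RS",
                     float(rng.uniform(0.5, 1.0)))
                for x, d in zip(rng.integers(0, 8, n_pred), rng.integers(0, 8, n_pred))
            ]
            got = average_precision(pred, truth, 0.5)
            # independent oracle: greedy matching over ranked predictions,
            # then AP as the mean over 101 recall points of the maximum
            # precision among prefixes reaching that recall
            ranked = sorted(pred, key=lambda p: -p.top_conf)
            claimed = [False] * len(truth)
            flags = []
            for p in ranked:
                ious = [
                    (box_iou(p.box, t.box), j)
                    for j, t in enumerate(truth) if not claimed[j]
                ]
                ious = [(v, j) for v, j in ious if v >= 0.5]
                if ious:
                    v, j = max(ious)
                    claimed[j] = True
                    flags.append(True)
                else:
                    flags.append(False)
            prefix = []
            tp = 0
            for k, hit in enumerate(flags, start=1):
                tp += hit
                prefix.append((tp / len(truth), tp / k))
            total = 0.0
            for r in np.linspace(0, 1, 101):
                cands = [p for rec, p in prefix if rec >= r]
                total += max(cands) if cands else 0.0
            expect = 100 * total / 101
            assert got == pytest.approx(expect, abs=1e-9)


class TestPixelMetrics:
    def test_identical_labels_all_ones(self, rng):
        seg = rng.integers(0, 4, size=(40, 40))
        pm = pixel_metrics(seg, seg)
        assert (pm.pixel_accuracy, pm.mean_accuracy, pm.mean_iu,
                pm.frequency_weighted_iu) == (1.0, 1.0, 1.0, 1.0)

    def test_all_background_prediction_hand_counted(self):
        """Truth half class-1, prediction all class-0: metrics follow from
        n00=50, n10=50 by direct formula evaluation."""
        truth = np.zeros((10, 10), dtype=int)
        truth[:5] = 1
        pred = np.zeros((10, 10), dtype=int)
        pm = pixel_metrics(pred, truth)
        assert pm.pixel_accuracy == pytest.approx(0.5)
        assert pm.mean_accuracy == pytest.approx(0.5)
        assert pm.mean_iu == pytest.approx(0.25)
        assert pm.frequency_weighted_iu == pytest.approx(0.25)

    def test_matches_brute_force_counts(self, rng):
        """All four metrics agree with an explicit per-class loop on 200
        random label images."""
        for _ in range(200):
            k = int(rng.integers(2, 5))
            truth = rng.integers(0, k, size=(12, 12))
            pred = rng.integers(0, k, size=(12, 12))
            pm = pixel_metrics(pred, truth)
            accs, ius, ts = [], [], []
            for i in range(k):
                t_i = int((truth == i).sum())
                if t_i == 0:
                    continue
                n_ii = int(((truth == i) & (pred == i)).sum())
                p_i = int((pred == i).sum())
                accs.append(n_ii / t_i)
                ius.append(n_ii / (t_i + p_i - n_ii))
                ts.append(t_i)
            total = truth.size
            diag = sum(int(((truth == i) & (pred == i)).sum()) for i in range(k))
            assert pm.pixel_accuracy == pytest.approx(diag / total)
            assert pm.mean_accuracy == pytest.approx(np.mean(accs))
            assert pm.mean_iu == pytest.approx(np.mean(ius))
            assert pm.frequency_weighted_iu == pytest.approx(
                sum(t * u for t, u in zip(ts, ius)) / total
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_metrics(np.zeros((4, 4), dtype=int), np.zeros((5, 5), dtype=int))


class TestStagingAgreement:
    def test_identical_stagings_are_100_percent(self):
        staging = {i: "I-V" for i in range(10)}
        stats = staging_agreement(staging, dict(staging))
        assert stats.percent == 100.0

    def test_whole_testis_contingency_with_reconciliation(self):
        """112 tubules with 107 exact agreements is 95.5%; reconciling 4
        borderline cross-sections raises it to 111/112 = 99.1%."""
        human = {i: "I-V" for i in range(112)}
        model = dict(human)
        for i in range(4):       # borderline early/mid-stage disagreements
            model[i] = "VI-VIII"
        model[4] = "XII"         # one genuine conflict
        stats = staging_agreement(human, model)
        assert (stats.n_total, stats.n_agree) == (112, 107)
        assert stats.percent == 95.5
        reconciled = {i: "VI-VIII" for i in range(4)}
        stats2 = staging_agreement(human, model, reconciled=reconciled)
        assert stats2.n_agree == 111
        assert stats2.percent == 99.1

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            staging_agreement({1: "IX"}, {2: "IX"})
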