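"""Detection, segmentation, and staging-agreement metrics.

Covers IOU-matched per-class PPV/sensitivity/F1, a 9x9 confusion matrix,
COCO-style average precision with 101-point interpolation, the four
classical pixel-level segmentation metrics (pixel accuracy, mean accuracy,
mean IU, frequency-weighted IU), and human-vs-model staging agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classes import CELL_CLASSES
from .geometry import BoundingBox, box_iou
from .types import CellDetection

MATCH_IOU_MIN = 0.5


@dataclass(frozen=True)
class GroundTruthBox:
    box: BoundingBox
    cls: str


@dataclass
class MatchResult:
    """Outcome of greedy prediction/truth matching at a fixed IOU."""

    pairs: list[tuple[CellDetection, GroundTruthBox]]
    false_positives: list[CellDetection]
    false_negatives: list[GroundTruthBox]
    iou_min: float = MATCH_IOU_MIN


def match_detections(
    pred: Sequence[CellDetection],
    truth: Sequence[GroundTruthBox],
    iou_min: float = MATCH_IOU_MIN,
    class_aware: bool = False,
) -> MatchResult:
    """Greedy one-to-one matching: predictions in descending confidence each
    claim the unclaimed truth with highest IOU >= ``iou_min``.

    Matching is class-agnostic by default (classification quality is scored
    afterwards, enabling the confusion matrix); ``class_aware=True``
    restricts candidates to same-class truths.
    """
    order = sorted(range(len(pred)), key=lambda i: (-pred[i].top_conf, i))
    claimed = [False] * len(truth)
    pairs = []
    fps = []
    for i in order:
        p = pred[i]
        best_j, best_iou = -1, iou_min
        for j, t in enumerate(truth):
            if claimed[j]:
                continue
            if class_aware and t.cls != p.top_class:
                continue
            v = box_iou(p.box, t.box)
            if v > best_iou or (v == best_iou and best_j == -1 and v >= iou_min):
                best_j, best_iou = j, v
        if best_j >= 0:
            claimed[best_j] = True
            pairs.append((p, truth[best_j]))
        else:
            fps.append(p)
    fns = [t for j, t in enumerate(truth) if not claimed[j]]
    return MatchResult(pairs=pairs, false_positives=fps, false_negatives=fns, iou_min=iou_min)


def f1_score(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of positive predictive value and sensitivity."""
    if ppv + sensitivity == 0:
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


@dataclass
class ClassPRF:
    ppv: Optional[float]
    sensitivity: Optional[float]
    f1: Optional[float]
    tp: int
    n_pred: int
    n_truth: int


def detection_prf(match: MatchResult, classes: Sequence[str] = CELL_CLASSES) -> dict[str, ClassPRF]:
    """Per-class PPV / sensitivity / F1 on a completed matching.

    TP for class c counts matched pairs where both labels are c. Ratios with
    zero denominator are reported as None (undefined), never as 0.
    """
    out: dict[str, ClassPRF] = {}
    for c in classes:
        tp = sum(1 for p, t in match.pairs if p.top_class == c and t.cls == c)
        n_pred = (
            sum(1 for p, _ in match.pairs if p.top_class == c)
            + sum(1 for p in match.false_positives if p.top_class == c)
        )
        n_truth = (
            sum(1 for _, t in match.pairs if t.cls == c)
            + sum(1 for t in match.false_negatives if t.cls == c)
        )
        ppv = tp / n_pred if n_pred else None
        sens = tp / n_truth if n_truth else None
        f1 = f1_score(ppv, sens) if ppv is not None and sens is not None else None
        out[c] = ClassPRF(ppv=ppv, sensitivity=sens, f1=f1, tp=tp, n_pred=n_pred, n_truth=n_truth)
    return out


def macro_average(values: Mapping[str, Optional[float]] | Sequence[Optional[float]]) -> float:
    """Unweighted mean over defined (non-None) per-class values."""
    vals = list(values.values()) if isinstance(values, Mapping) else list(values)
    defined = [v for v in vals if v is not None]
    if not defined:
        raise ValueError("macro_average needs at least one defined value")
    return float(np.mean(defined))


def confusion_matrix(match: MatchResult, classes: Sequence[str] = CELL_CLASSES) -> pd.DataFrame:
    """Counts of (true class, predicted class) over matched pairs."""
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for p, t in match.pairs:
        mat.loc[t.cls, p.top_class] += 1
    return mat


# ---------------------------------------------------------------------------
# COCO-style average precision
# ---------------------------------------------------------------------------

def _class_ap(pred: list[CellDetection], truth: list[GroundTruthBox], iou_min: float) -> float:
    """101-point interpolated AP for one class."""
    if not truth:
        return float("nan")
    pred = sorted(pred, key=lambda p: -p.top_conf)
    claimed = [False] * len(truth)
    tp = np.zeros(len(pred))
    for i, p in enumerate(pred):
        best_j, best_iou = -1, iou_min
        for j, t in enumerate(truth):
            if claimed[j]:
                continue
            v = box_iou(p.box, t.box)
            if v >= best_iou and (best_j == -1 or v > best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            claimed[best_j] = True
            tp[i] = 1.0
    if not len(pred):
        return 0.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / len(truth)
    precision = cum_tp / np.arange(1, len(pred) + 1)
    # monotone precision envelope, then 101-point sampling
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        idx = np.searchsorted(recall, r, side="left")
        ap += precision[idx] if idx < len(precision) else 0.0
    return ap / 101.0


def average_precision(
    pred: Sequence[CellDetection],
    truth: Sequence[GroundTruthBox],
    iou_min: float = MATCH_IOU_MIN,
    classes: Sequence[str] = CELL_CLASSES,
) -> float:
    """Mean AP over classes with at least one truth, scaled to [0, 100]."""
    aps = []
    for c in classes:
        tc = [t for t in truth if t.cls == c]
        if not tc:
            continue
        pc = [p for p in pred if p.top_class == c]
        aps.append(_class_ap(pc, tc, iou_min))
    if not aps:
        raise ValueError("no ground-truth objects for any class")
    return 100.0 * float(np.mean(aps))


# ---------------------------------------------------------------------------
# pixel-level segmentation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelMetrics:
    pixel_accuracy: float
    mean_accuracy: float
    mean_iu: float
    frequency_weighted_iu: float


def pixel_metrics(pred_seg: np.ndarray, truth_seg: np.ndarray) -> PixelMetrics:
    """The four classical semantic-segmentation metrics.

    With n_ij = pixels of true class i predicted as class j and
    t_i = sum_j n_ij:

    * pixel accuracy      = sum_i n_ii / sum_i t_i
    * mean accuracy       = mean_i (n_ii / t_i)
    * mean IU             = mean_i (n_ii / (t_i + sum_j n_ji - n_ii))
    * freq.-weighted IU   = sum_i t_i * IU_i / sum_k t_k

    Means are taken over classes present in the truth (t_i > 0).
    """
    pred_seg = np.asarray(pred_seg)
    truth_seg = np.asarray(truth_seg)
    if pred_seg.shape != truth_seg.shape:
        raise ValueError(f"shape mismatch {pred_seg.shape} vs {truth_seg.shape}")
    n_cls = int(max(pred_seg.max(), truth_seg.max())) + 1
    n = np.bincount(
        (truth_seg.astype(np.int64) * n_cls + pred_seg.astype(np.int64)).ravel(),
        minlength=n_cls * n_cls,
    ).reshape(n_cls, n_cls)
    t = n.sum(axis=1)
    present = t > 0
    diag = np.diag(n)
    pixel_acc = diag.sum() / t.sum()
    mean_acc = float(np.mean(diag[present] / t[present]))
    denom = t + n.sum(axis=0) - diag
    iu = np.where(denom > 0, diag / np.maximum(denom, 1), 0.0)
    mean_iu = float(np.mean(iu[present]))
    fw_iu = float((t[present] * iu[present]).sum() / t.sum())
    return PixelMetrics(float(pixel_acc), mean_acc, mean_iu, fw_iu)


# ---------------------------------------------------------------------------
# staging agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementStats:
    n_total: int
    n_agree: int
    percent: float


def staging_agreement(
    human: Mapping[object, str],
    model: Mapping[object, str],
    reconciled: Mapping[object, str] | None = None,
) -> AgreementStats:
    """Exact stage-class agreement between two per-tubule stagings.

    ``reconciled`` optionally overrides the human stage for named tubules
    (consensus after review of borderline cross-sections) before counting.
    Percent is 100 * n_agree / n rounded to one decimal.
    """
    if set(human) != set(model):
        raise ValueError("human and model stagings must cover the same tubule ids")
    eff = dict(human)
    if reconciled:
        unknown = set(reconciled) - set(eff)
        if unknown:
            raise ValueError(f"reconciled overrides for unknown tubules: {sorted(unknown)!r}")
        eff.update(reconciled)
    n = len(eff)
    n_agree = sum(1 for k in eff if eff[k] == model[k])
    return AgreementStats(n_total=n, n_agree=n_agree, percent=round(100.0 * n_agree / n, 1))


@dataclass
class MetricsReport:
    """Bundle of everything the evaluation stage can report."""

    prf: dict[str, ClassPRF] = field(default_factory=dict)
    macro_ppv: Optional[float] = None
    macro_sensitivity: Optional[float] = None
    macro_f1: Optional[float] = None
    confusion: Optional[pd.DataFrame] = None
    ap50: Optional[float] = None
    ap75: Optional[float] = None
    pixels: Optional[PixelMetrics] = None
    agreement: Optional[AgreementStats] = None

    def to_dict(self) -> dict:
        out: dict = {
            "per_class": {
                c: {"ppv": v.ppv, "sensitivity": v.sensitivity, "f1": v.f1,
                    "tp": v.tp, "n_pred": v.n_pred, "n_truth": v.n_truth}
                for c, v in self.prf.items()
            },
            "macro_ppv": self.macro_ppv,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_f1": self.macro_f1,
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.to_dict()
        if self.ap50 is not None:
            out["ap50"] = self.ap50
        if self.ap75 is not None:
            out["ap75"] = self.ap75
        if self.pixels is not None:
            from dataclasses import asdict

            out["pixel_metrics"] = asdict(self.pixels)
        if self.agreement is not None:
            out["agreement"] = {
                "n_total": self.agreement.n_total,
                "n_agree": self.agreement.n_agree,
                "percent": self.agreement.percent,
            }
        return out


def evaluate_detections(
    pred: Sequence[CellDetection],
    truth: Sequence[GroundTruthBox],
    iou_min: float = MATCH_IOU_MIN,
    with_ap: bool = True,
) -> MetricsReport:
    """Convenience wrapper producing the standard detection report."""
    match = match_detections(pred, truth, iou_min=iou_min)
    prf = detection_prf(match)

    def _macro(attr: str):
        vals = [getattr(v, attr) for v in prf.values() if getattr(v, attr) is not None]
        return float(np.mean(vals)) if vals else None

    report = MetricsReport(
        prf=prf,
        macro_ppv=_macro("ppv"),
        macro_sensitivity=_macro("sensitivity"),
        macro_f1=_macro("f1"),
        confusion=confusion_matrix(match),
    )
    if with_ap and truth:
        report.ap50 = average_precision(pred, truth, 0.5)
        report.ap75 = average_precision(pred, truth, 0.75)
    return report
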