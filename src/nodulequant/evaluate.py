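"""Automated-vs-manual (or simulated-truth) detection evaluation.

Detections are matched to ground-truth nodules class-aware by mask IoU
with greedy one-to-one assignment in descending IoU order — the standard
object-detection evaluation convention.  Per-class and micro-averaged
precision/recall/F1 and signed count errors summarise where automation
agrees with curated truth.
"""

from __future__ import annotations

import dataclasses

from .core_io import CLASS_ORDER, Detection, FluorClass


@dataclasses.dataclass
class ClassMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = 1.0
    recall: float = 1.0
    f1: float = 1.0
    count_error: int = 0  # detected - truth


@dataclasses.dataclass
class EvalReport:
    per_class: dict
    precision: float
    recall: float
    f1: float
    iou_min: float

    def to_dict(self) -> dict:
        return {
            "iou_min": self.iou_min,
            "overall": {"precision": self.precision, "recall": self.recall,
                        "f1": self.f1},
            "per_class": {
                fc.value: dataclasses.asdict(m)
                for fc, m in self.per_class.items()
            },
        }


def mask_iou(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def match_detections(predicted: list[Detection], truth: list[Detection],
                     iou_min: float = 0.5) -> list[tuple[int, int, float]]:
    """Greedy one-to-one class-aware matching by mask IoU.

    Returns (predicted_index, truth_index, iou) triples.  Candidate pairs
    require identical class and IoU >= iou_min; pairs are consumed in
    descending IoU order with ties broken by lower truth index, then lower
    predicted index.  Unmatched predictions are false positives, unmatched
    truths false negatives.
    """
    if not 0.0 < iou_min <= 1.0:
        raise ValueError("iou_min must lie in (0, 1]")
    candidates = []
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(truth):
            if p.fluor_class is not t.fluor_class:
                continue
            iou = mask_iou(p.mask, t.mask)
            if iou >= iou_min:
                candidates.append((iou, ti, pi))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_p: set[int] = set()
    matched_t: set[int] = set()
    matches = []
    for iou, ti, pi in candidates:
        if pi in matched_p or ti in matched_t:
            continue
        matched_p.add(pi)
        matched_t.add(ti)
        matches.append((pi, ti, iou))
    return matches


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def eval_metrics(matches: list[tuple[int, int, float]],
                 predicted: list[Detection], truth: list[Detection],
                 iou_min: float = 0.5) -> EvalReport:
    """Per-class and micro-averaged precision/recall/F1 from a match set.

    When a denominator is zero the metric is 1.0 (no errors possible);
    a computed 0/(n>0) stays 0.
    """
    matched_p = {pi for pi, _, _ in matches}
    matched_t = {ti for _, ti, _ in matches}
    per_class = {}
    tot_tp = tot_fp = tot_fn = 0
    for fc in CLASS_ORDER:
        preds = [i for i, p in enumerate(predicted) if p.fluor_class is fc]
        trs = [i for i, t in enumerate(truth) if t.fluor_class is fc]
        tp = sum(1 for i in trs if i in matched_t)
        fp = sum(1 for i in preds if i not in matched_p)
        fn = sum(1 for i in trs if i not in matched_t)
        precision, recall, f1 = _prf(tp, fp, fn)
        per_class[fc] = ClassMetrics(tp=tp, fp=fp, fn=fn, precision=precision,
                                     recall=recall, f1=f1,
                                     count_error=len(preds) - len(trs))
        tot_tp += tp
        tot_fp += fp
        tot_fn += fn
    precision, recall, f1 = _prf(tot_tp, tot_fp, tot_fn)
    return EvalReport(per_class=per_class, precision=precision, recall=recall,
                      f1=f1, iou_min=iou_min)


def evaluate(predicted: list[Detection], truth: list[Detection],
             iou_min: float = 0.5) -> EvalReport:
    """Match then score in one call."""
    matches = match_detections(predicted, truth, iou_min)
    return eval_metrics(matches, predicted, truth, iou_min)
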