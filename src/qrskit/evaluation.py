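"""Tolerance-matched detection F1 and per-class / micro / macro
classification F1.

A predicted beat is a true positive when it lies within 0.1 s (inclusive)
of a reference annotation, under a maximum-cardinality one-to-one matching.
Classification metrics by default include detection errors: an undetected
PVC counts as a PVC false negative, a spurious prediction as a false
positive of its predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .records_io import BeatClass

__all__ = [
    "TOLERANCE_S",
    "MatchResult",
    "MetricsReport",
    "match_beats",
    "detection_f1",
    "classification_f1",
    "evaluate_dataset",
]

TOLERANCE_S = 0.1
_CLASS_NAMES = ("N", "PAC", "PVC")


@dataclass
class MatchResult:
    """One-to-one matching between predicted and reference beat times."""

    pairs: list[tuple[int, int, float]]  # (pred idx, ref idx, offset s)
    unmatched_pred: list[int]
    unmatched_ref: list[int]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_ref)


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    detection_f1: float
    class_f1: dict[str, float] = field(default_factory=dict)
    micro_f1: float = float("nan")
    macro_f1: float = float("nan")
    confusion: dict[str, dict[str, int]] = field(default_factory=dict)
    per_record: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "detection_f1": self.detection_f1,
            "class_f1": self.class_f1,
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion,
            "per_record": self.per_record,
        }


def match_beats(
    predicted: np.ndarray | list[float],
    reference: np.ndarray | list[float],
    tolerance_s: float = TOLERANCE_S,
) -> MatchResult:
    """Maximum-cardinality one-to-one matching under |dt| <= tolerance.

    Among maximum-cardinality matchings, the one minimizing total |dt| is
    chosen (solved as a rectangular assignment problem).  Inputs must be
    sorted ascending.
    """
    pred = np.asarray(predicted, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if np.any(np.diff(pred) < 0) or np.any(np.diff(ref) < 0):
        raise ValueError("beat time lists must be sorted ascending")

    if pred.size == 0 or ref.size == 0:
        return MatchResult(
            pairs=[],
            unmatched_pred=list(range(pred.size)),
            unmatched_ref=list(range(ref.size)),
        )

    offsets = pred[:, None] - ref[None, :]
    feasible = np.abs(offsets) <= tolerance_s + 1e-12
    # large constant makes min-cost assignment equivalent to max cardinality
    big = 1e9
    cost = np.where(feasible, np.abs(offsets), big)
    rows, cols = linear_sum_assignment(cost)

    pairs = []
    matched_pred, matched_ref = set(), set()
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            pairs.append((int(i), int(j), float(offsets[i, j])))
            matched_pred.add(int(i))
            matched_ref.add(int(j))
    return MatchResult(
        pairs=pairs,
        unmatched_pred=[i for i in range(pred.size) if i not in matched_pred],
        unmatched_ref=[j for j in range(ref.size) if j not in matched_ref],
    )


def _f1(tp: int, fp: int, fn: int) -> float:
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def detection_f1(match: MatchResult) -> float:
    """F1 = 2TP / (2TP + FP + FN); empty-vs-empty is defined as 1.0."""
    return _f1(match.tp, match.fp, match.fn)


def classification_f1(
    match: MatchResult,
    predicted_classes: list[BeatClass],
    reference_classes: list[BeatClass],
    include_detection_errors: bool = True,
) -> MetricsReport:
    """Per-class, micro and macro F1 over {N, PAC, PVC}.

    For a matched pair with differing classes, the predicted class gains a
    false positive and the reference class a false negative.  When
    ``include_detection_errors`` (default), unmatched predictions and
    references also count as FP/FN of their classes; disable to condition
    on successful detection only.
    """
    counts = {c: {"tp": 0, "fp": 0, "fn": 0} for c in _CLASS_NAMES}
    confusion = {r: {p: 0 for p in _CLASS_NAMES} for r in _CLASS_NAMES}

    for pi, ri, _ in match.pairs:
        p, r = predicted_classes[pi].name, reference_classes[ri].name
        confusion[r][p] += 1
        if p == r:
            counts[p]["tp"] += 1
        else:
            counts[p]["fp"] += 1
            counts[r]["fn"] += 1
    if include_detection_errors:
        for pi in match.unmatched_pred:
            counts[predicted_classes[pi].name]["fp"] += 1
        for ri in match.unmatched_ref:
            counts[reference_classes[ri].name]["fn"] += 1

    class_f1 = {c: _f1(**counts[c]) for c in _CLASS_NAMES}
    pooled = {k: sum(counts[c][k] for c in _CLASS_NAMES) for k in ("tp", "fp", "fn")}
    return MetricsReport(
        tp=match.tp,
        fp=match.fp,
        fn=match.fn,
        detection_f1=detection_f1(match),
        class_f1=class_f1,
        micro_f1=_f1(**pooled),
        macro_f1=float(np.mean([class_f1[c] for c in _CLASS_NAMES])),
        confusion=confusion,
    )


def evaluate_dataset(
    detections: dict[str, tuple[list[float], list[BeatClass]]],
    references: dict[str, tuple[list[float], list[BeatClass]]],
    tolerance_s: float = TOLERANCE_S,
    include_detection_errors: bool = True,
) -> MetricsReport:
    """Pool counts across records sharing ids; also reports per-record F1.

    ``detections`` / ``references`` map record_id to (sorted beat times in
    seconds, parallel class list).
    """
    missing = sorted(set(references) ^ set(detections))
    if missing:
        raise ValueError(f"record id mismatch between detections and references: {missing}")

    pooled = {c: {"tp": 0, "fp": 0, "fn": 0} for c in _CLASS_NAMES}
    confusion = {r: {p: 0 for p in _CLASS_NAMES} for r in _CLASS_NAMES}
    det_tp = det_fp = det_fn = 0
    per_record = []

    for record_id in sorted(references):
        pred_times, pred_classes = detections[record_id]
        ref_times, ref_classes = references[record_id]
        match = match_beats(pred_times, ref_times, tolerance_s)
        det_tp += match.tp
        det_fp += match.fp
        det_fn += match.fn
        for pi, ri, _ in match.pairs:
            confusion[ref_classes[ri].name][pred_classes[pi].name] += 1
        _accumulate_class_counts(
            pooled, match, list(pred_classes), list(ref_classes),
            include_detection_errors,
        )
        per_record.append(
            {
                "record_id": record_id,
                "tp": match.tp,
                "fp": match.fp,
                "fn": match.fn,
                "detection_f1": detection_f1(match),
            }
        )

    class_f1 = {c: _f1(**pooled[c]) for c in _CLASS_NAMES}
    total = {k: sum(pooled[c][k] for c in _CLASS_NAMES) for k in ("tp", "fp", "fn")}
    return MetricsReport(
        tp=det_tp,
        fp=det_fp,
        fn=det_fn,
        detection_f1=_f1(det_tp, det_fp, det_fn),
        class_f1=class_f1,
        micro_f1=_f1(**total),
        macro_f1=float(np.mean([class_f1[c] for c in _CLASS_NAMES])),
        confusion=confusion,
        per_record=per_record,
    )


def _accumulate_class_counts(
    pooled: dict,
    match: MatchResult,
    predicted_classes: list[BeatClass],
    reference_classes: list[BeatClass],
    include_detection_errors: bool,
) -> None:
    for pi, ri, _ in match.pairs:
        p, r = predicted_classes[pi].name, reference_classes[ri].name
        if p == r:
            pooled[p]["tp"] += 1
        else:
            pooled[p]["fp"] += 1
            pooled[r]["fn"] += 1
    if include_detection_errors:
        for pi in match.unmatched_pred:
            pooled[predicted_classes[pi].name]["fp"] += 1
        for ri in match.unmatched_ref:
            pooled[reference_classes[ri].name]["fn"] += 1


def mean_std_across_datasets(f1_scores: list[float]) -> tuple[float, float]:
    """Mean +/- population standard deviation across dataset-level scores."""
    arr = np.asarray(f1_scores, dtype=np.float64)
    return float(arr.mean()), float(arr.std())
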