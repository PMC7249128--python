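"""Scoring detections against ground truth.

Detections are matched to ground-truth stems frame by frame using
bottom-row span overlap: a detection and a stem match when their spans
overlap by at least half the narrower span (one-to-one, best overlap
first).  This is the machine analogue of visually confirming that a
detected contour is one complete solid stem at the bottom row.

Reported variables follow the field-validation bookkeeping: correctly
detected, falsely detected and undetected counts (correct + false =
total detections; correct + undetected = total stems), the share of
false positives explained by branch objects, and diameter RMSE overall
and per diameter class group (28.57–34.92 mm vs > 34.92 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DetectionSpan", "EvalReport", "evaluate_frames", "evaluate_csv", "span_overlap"]

_CLASS_SPLIT_MM = 34.92  # boundary between the low and high diameter class groups


@dataclass(frozen=True)
class DetectionSpan:
    """Minimal view of one detection: bottom-row span + estimated diameter."""

    span: tuple[int, int]
    diameter_mm: float


def span_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap length of two half-open column intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _matches(a: tuple[int, int], b: tuple[int, int]) -> bool:
    narrower = min(a[1] - a[0], b[1] - b[0])
    return narrower > 0 and span_overlap(a, b) * 2 >= narrower


@dataclass
class EvalReport:
    """Suite-level detection and diameter-accuracy metrics."""

    n_stems: int = 0
    n_detections: int = 0
    n_correct: int = 0
    n_false: int = 0
    n_undetected: int = 0
    n_false_branch: int = 0
    diameter_errors_mm: list[float] = field(default_factory=list)
    true_diameters_mm: list[float] = field(default_factory=list)

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_stems if self.n_stems else float("nan")

    @property
    def correctly_detected_rate(self) -> float:
        return self.n_correct / self.n_detections if self.n_detections else float("nan")

    @property
    def falsely_detected_rate(self) -> float:
        return self.n_false / self.n_detections if self.n_detections else float("nan")

    @property
    def branch_share_of_false(self) -> float:
        return self.n_false_branch / self.n_false if self.n_false else float("nan")

    def rmse_mm(self, class_group: str = "all") -> float:
        """Diameter RMSE, overall or for one class group (low / high)."""
        err = np.asarray(self.diameter_errors_mm)
        true = np.asarray(self.true_diameters_mm)
        if class_group == "low":
            err = err[true <= _CLASS_SPLIT_MM]
        elif class_group == "high":
            err = err[true > _CLASS_SPLIT_MM]
        elif class_group != "all":
            raise ValueError("class_group must be 'all', 'low' or 'high'")
        return float(np.sqrt(np.mean(err**2))) if err.size else float("nan")

    def as_dict(self) -> dict:
        return {
            "n_stems": self.n_stems,
            "n_detections": self.n_detections,
            "n_correct": self.n_correct,
            "n_false": self.n_false,
            "n_undetected": self.n_undetected,
            "n_false_branch": self.n_false_branch,
            "recall": self.recall,
            "correctly_detected_rate": self.correctly_detected_rate,
            "falsely_detected_rate": self.falsely_detected_rate,
            "branch_share_of_false": self.branch_share_of_false,
            "rmse_mm": self.rmse_mm(),
            "rmse_mm_low_class": self.rmse_mm("low"),
            "rmse_mm_high_class": self.rmse_mm("high"),
        }


def evaluate_frames(
    detections: Mapping[int, Sequence[DetectionSpan]],
    truth: Mapping[int, Sequence],
) -> EvalReport:
    """Match detections to ground truth per frame and accumulate metrics.

    ``truth`` maps frame ids to objects exposing ``kind``, ``span`` and
    ``diameter_mm`` (e.g. :class:`salixmap.synthetic.GroundTruthObject`).
    The frame sets must agree exactly.
    """
    if set(detections) != set(truth):
        raise ValueError("detections and ground truth cover different frames")
    report = EvalReport()
    for frame_id in sorted(truth):
        dets = list(detections[frame_id])
        stems = [o for o in truth[frame_id] if o.kind == "stem"]
        branches = [o for o in truth[frame_id] if o.kind == "branch"]
        report.n_stems += len(stems)
        report.n_detections += len(dets)

        pairs = [
            (span_overlap(d.span, s.span), di, si)
            for di, d in enumerate(dets)
            for si, s in enumerate(stems)
            if _matches(d.span, s.span)
        ]
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        used_d: set[int] = set()
        used_s: set[int] = set()
        for _, di, si in pairs:
            if di in used_d or si in used_s:
                continue
            used_d.add(di)
            used_s.add(si)
            report.n_correct += 1
            report.diameter_errors_mm.append(
                dets[di].diameter_mm - stems[si].diameter_mm
            )
            report.true_diameters_mm.append(stems[si].diameter_mm)

        report.n_undetected += len(stems) - len(used_s)
        for di, d in enumerate(dets):
            if di in used_d:
                continue
            report.n_false += 1
            if any(_matches(d.span, b.span) for b in branches if b.span[1] > b.span[0]):
                report.n_false_branch += 1
    return report


def evaluate_csv(detections_csv, ground_truth_csv) -> EvalReport:
    """Score a detections CSV against a generator ground-truth CSV."""
    det = pd.read_csv(detections_csv)
    gt = pd.read_csv(ground_truth_csv)

    @dataclass(frozen=True)
    class _Obj:
        kind: str
        span: tuple[int, int]
        diameter_mm: float

    det_map: dict[int, list[DetectionSpan]] = {
        int(fid): [
            DetectionSpan((int(r.span_start), int(r.span_end)), float(r.diameter_mm))
            for r in grp.itertuples()
        ]
        for fid, grp in det.groupby("frame_id")
    }
    gt_map: dict[int, list[_Obj]] = {
        int(fid): [
            _Obj(str(r.kind), (int(r.span_start), int(r.span_end)), float(r.diameter_mm))
            for r in grp.itertuples()
        ]
        for fid, grp in gt.groupby("frame_id")
    }
    for fid in gt_map:
        det_map.setdefault(fid, [])
    return evaluate_frames(det_map, gt_map)
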