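"""Detector-output fusion and detection evaluation.

The package never runs an object detector itself: it consumes per-image
prediction text files in the common detector dialect
``class cx cy w h conf`` (coordinates normalized to [0, 1]), fuses two
detectors' outputs by IoU matching with averaged confidence, and scores
predictions against ground-truth boxes by greedy one-to-one matching.

Thresholds follow the two-detector ensemble protocol: predictions from two
models referring to the same image are considered the same finding when their
IoU exceeds 0.3, in which case the fused confidence is the mean of the two.
A prediction left unmatched keeps its box but has its confidence halved (the
mean with an absent partner treated as zero) -- which is why evaluation of
the ensemble uses a confidence floor of 0.05 instead of the single-model 0.1.
Evaluation counts a true positive when a prediction overlaps an unmatched
ground-truth box with IoU strictly greater than 0.1.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "DetectionEvalResult",
    "iou",
    "fuse_ensemble",
    "evaluate_detection",
    "reclassify_false_positives",
    "read_predictions",
]

Box = tuple[float, float, float, float]  # (x, y, w, h), top-left, half-open


@dataclass(frozen=True)
class Detection:
    """A predicted box with confidence and source-model tag."""

    image_id: str
    bbox: Box
    confidence: float
    source: str = "model_a"  # model_a | model_b | ensemble

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class DetectionEvalResult:
    """Per-image match table plus TP/FP/FN counts and recall/precision."""

    tp: int
    fp: int
    fn: int
    iou_min: float
    conf_min: float
    matches: list[dict] = field(default_factory=list)  # per-prediction records
    fp_ids: list[str] = field(default_factory=list)  # ids of FP predictions

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "recall": self.recall, "precision": self.precision,
            "iou_min": self.iou_min, "conf_min": self.conf_min,
            "matches": self.matches,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        warnings.warn("zero-area box in IoU; returning 0")
        return 0.0
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    # rounding in (x+w)-x can push the ratio epsilon past 1 for equal boxes
    return min(1.0, max(0.0, inter / union))


def fuse_ensemble(preds_a: list[Detection], preds_b: list[Detection],
                  iou_thresh: float = 0.3,
                  box_rule: str = "higher_confidence") -> list[Detection]:
    """Fuse two detectors' predictions into ensemble detections.

    Per image, pairs with IoU strictly greater than `iou_thresh` are merged
    greedily in descending-IoU order (one-to-one); the fused confidence is
    the mean of the pair.  Unmatched predictions are retained with their
    confidence halved.  The merged box is the higher-confidence member's
    (ties break toward model A); `box_rule="weighted"` instead averages the
    two boxes weighted by confidence.  Output is sorted by descending
    confidence.
    """
    images = sorted({d.image_id for d in preds_a} | {d.image_id for d in preds_b})
    fused: list[Detection] = []
    for img in images:
        da = [d for d in preds_a if d.image_id == img]
        db = [d for d in preds_b if d.image_id == img]
        pairs = [(iou(a.bbox, b.bbox), i, j)
                 for i, a in enumerate(da) for j, b in enumerate(db)]
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for ov, i, j in pairs:
            if ov <= iou_thresh or i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            a, b = da[i], db[j]
            conf = (a.confidence + b.confidence) / 2.0
            if box_rule == "weighted":
                wa = a.confidence / (a.confidence + b.confidence or 1.0)
                box = tuple(wa * np.asarray(a.bbox) + (1 - wa) * np.asarray(b.bbox))
            else:
                box = a.bbox if a.confidence >= b.confidence else b.bbox
            fused.append(Detection(img, tuple(box), conf, source="ensemble"))
        for i, a in enumerate(da):
            if i not in used_a:
                fused.append(Detection(img, a.bbox, a.confidence / 2.0,
                                       source="ensemble"))
        for j, b in enumerate(db):
            if j not in used_b:
                fused.append(Detection(img, b.bbox, b.confidence / 2.0,
                                       source="ensemble"))
    fused.sort(key=lambda d: -d.confidence)
    return fused


def evaluate_detection(preds: list[Detection],
                       ground_truth: dict[str, list[Box]],
                       iou_min: float = 0.1,
                       conf_min: float = 0.1) -> DetectionEvalResult:
    """Score predictions against ground-truth boxes.

    Predictions below `conf_min` are discarded; the rest are matched greedily
    in descending-confidence order, each ground-truth box claimable once, a
    match requiring IoU strictly greater than `iou_min`.  Matched predictions
    are TPs, unmatched predictions FPs, unclaimed ground-truth boxes FNs.
    Images with predictions but no ground-truth entry contribute FPs only.
    """
    if not 0.0 <= conf_min <= 1.0:
        raise ValueError("conf_min must be in [0, 1]")
    kept = sorted((d for d in preds if d.confidence > conf_min),
                  key=lambda d: -d.confidence)
    claimed: dict[str, set[int]] = {img: set() for img in ground_truth}
    tp = fp = 0
    matches: list[dict] = []
    fp_ids: list[str] = []
    for k, d in enumerate(kept):
        gts = ground_truth.get(d.image_id)
        if gts is None:
            log.warning("image %s has predictions but no ground truth; "
                        "counting as false positives", d.image_id)
            gts = []
        best = None
        best_iou = iou_min
        for g_idx, g in enumerate(gts):
            if g_idx in claimed.get(d.image_id, set()):
                continue
            ov = iou(d.bbox, g)
            if ov > best_iou:
                best_iou, best = ov, g_idx
        pred_id = f"{d.image_id}#{k}"
        if best is not None:
            claimed.setdefault(d.image_id, set()).add(best)
            tp += 1
            matches.append({"pred_id": pred_id, "image_id": d.image_id,
                            "gt_index": best, "iou": best_iou,
                            "confidence": d.confidence, "outcome": "TP"})
        else:
            fp += 1
            fp_ids.append(pred_id)
            matches.append({"pred_id": pred_id, "image_id": d.image_id,
                            "gt_index": None, "iou": None,
                            "confidence": d.confidence, "outcome": "FP"})
    fn = sum(len(gts) - len(claimed.get(img, set()))
             for img, gts in ground_truth.items())
    return DetectionEvalResult(tp=tp, fp=fp, fn=fn, iou_min=iou_min,
                               conf_min=conf_min, matches=matches,
                               fp_ids=fp_ids)


def reclassify_false_positives(result: DetectionEvalResult,
                               accepted_fp_ids: set[str]) -> DetectionEvalResult:
    """Clinical-feedback correction: reviewer-accepted false positives become
    true positives backed by new ground-truth findings (FN unchanged)."""
    current = set(result.fp_ids)
    unknown = set(accepted_fp_ids) - current
    if unknown:
        raise ValueError(f"ids not in the current FP set: {sorted(unknown)}")
    k = len(accepted_fp_ids)
    matches = []
    for m in result.matches:
        if m["outcome"] == "FP" and m["pred_id"] in accepted_fp_ids:
            m = {**m, "outcome": "TP", "reclassified": True}
        matches.append(m)
    return replace(result, tp=result.tp + k, fp=result.fp - k,
                   matches=matches,
                   fp_ids=[i for i in result.fp_ids if i not in accepted_fp_ids])


def write_fp_review_csv(result: DetectionEvalResult, path: str | Path) -> Path:
    """CSV of current false positives for radiologist review; the reviewer
    fills the `accepted` column with yes/no."""
    import csv

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    by_id = {m["pred_id"]: m for m in result.matches}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pred_id", "image_id", "confidence", "accepted"])
        for fp_id in result.fp_ids:
            m = by_id[fp_id]
            w.writerow([fp_id, m["image_id"], m["confidence"], ""])
    return path


def read_accepted_fps(path: str | Path) -> set[str]:
    """Reviewer-accepted FP ids from a filled-in review CSV."""
    import csv

    accepted: set[str] = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["accepted"].strip().lower() in {"yes", "y", "true", "1"}:
                accepted.add(row["pred_id"])
    return accepted


def read_predictions(pred_dir: str | Path,
                     image_sizes: dict[str, tuple[int, int]] | tuple[int, int],
                     source: str = "model_a") -> list[Detection]:
    """Read per-image prediction txt files (``class cx cy w h conf``,
    normalized coordinates) and denormalize to pixel top-left boxes.

    `image_sizes` maps image id (the txt stem) to (height, width), or is one
    (height, width) applied to every image.
    """
    pred_dir = Path(pred_dir)
    out: list[Detection] = []
    for f in sorted(pred_dir.glob("*.txt")):
        image_id = f.stem
        if isinstance(image_sizes, dict):
            if image_id not in image_sizes:
                raise KeyError(f"no image size known for {image_id}")
            h, w = image_sizes[image_id]
        else:
            h, w = image_sizes
        for ln, line in enumerate(f.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{f}, line {ln}: expected 6 fields, "
                                 f"got {len(parts)}")
            try:
                _cls, cx, cy, bw, bh, conf = (parts[0], *map(float, parts[1:]))
            except ValueError as exc:
                raise ValueError(f"{f}, line {ln}: {exc}") from exc
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"{f}, line {ln}: confidence {conf} "
                                 "outside [0, 1]")
            box = (cx * w - bw * w / 2.0, cy * h - bh * h / 2.0,
                   bw * w, bh * h)
            out.append(Detection(image_id=image_id, bbox=box,
                                 confidence=conf, source=source))
    return out
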