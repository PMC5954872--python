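"""Region-based scoring: TP/FP matching, Sens/FPI, FROC, stage tables.

A detected ROI is a true positive when its overlap with a ground-truth
mass region exceeds 50% (overlap ratio = intersection / ground-truth
area by default; intersection-over-union is available).  Pooled over a
set of images,

    Sens = true positive marks / ground-truth regions,
    FPI  = false positive marks / images,

and the FROC curve traces (FPI, Sens) as the ROI score threshold sweeps
from the highest score downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GroundTruthRegion
from .verification import ROI

STAGE_NAMES = ("attention", "densification", "shape", "texture")


@dataclass
class MatchResult:
    """TP/FP bookkeeping for one image."""

    tp: int
    fp: int
    n_regions: int
    n_images: int = 1
    pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class FrocCurve:
    """Operating points (fpi, sens) ordered by non-decreasing FPI."""

    points: list[tuple[float, float]]
    thresholds: list[float]


def overlap_ratio(
    roi_mask: np.ndarray,
    gt_mask: np.ndarray,
    metric: str = "gt",
) -> float:
    """Overlap of a detection with a ground-truth mask.

    ``"gt"`` divides the intersection by the ground-truth area (how much
    of the annotated mass the detection covers); ``"iou"`` divides by the
    union.
    """
    inter = int((roi_mask & gt_mask).sum())
    if metric == "gt":
        denom = int(gt_mask.sum())
    elif metric == "iou":
        denom = int((roi_mask | gt_mask).sum())
    else:
        raise ValueError(f"unknown overlap metric {metric!r}")
    return inter / denom if denom else 0.0


def match(
    rois: list[ROI],
    gts: list[GroundTruthRegion],
    image_shape: tuple[int, int],
    overlap_min: float = 0.5,
    metric: str = "gt",
) -> MatchResult:
    """Greedy TP/FP matching of detections against annotations.

    All (roi, gt) overlaps are computed; pairs are consumed in order of
    descending overlap (ties broken by lower roi id then lower gt id),
    each ground truth and each ROI matching at most once.  Pairs qualify
    when overlap exceeds ``overlap_min``.  Unmatched ROIs are false
    positives.
    """
    gt_masks = [g.to_mask(image_shape) for g in gts]
    entries = []
    for ri, roi in enumerate(rois):
        for gi, gmask in enumerate(gt_masks):
            ov = overlap_ratio(roi.mask, gmask, metric)
            if ov > overlap_min:
                entries.append((ov, ri, gi))
    entries.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_roi: set[int] = set()
    used_gt: set[int] = set()
    pairs = []
    for ov, ri, gi in entries:
        if ri in used_roi or gi in used_gt:
            continue
        used_roi.add(ri)
        used_gt.add(gi)
        pairs.append((ri, gi))
    tp = len(pairs)
    fp = len(rois) - tp
    return MatchResult(tp=tp, fp=fp, n_regions=len(gts), pairs=pairs)


def sens_fpi(results: list[MatchResult]) -> tuple[float, float]:
    """Pooled sensitivity and false positives per image.

    Sens = sum TP / sum ground-truth regions (0 when there are none);
    FPI = sum FP / number of images.  Images without masses contribute
    to the FPI denominator.
    """
    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    n_regions = sum(r.n_regions for r in results)
    n_images = sum(r.n_images for r in results)
    sens = tp / n_regions if n_regions else 0.0
    fpi = fp / n_images if n_images else 0.0
    return sens, fpi


def froc(
    scored_rois: list[list[ROI]],
    gts: list[list[GroundTruthRegion]],
    image_shapes: list[tuple[int, int]],
    overlap_min: float = 0.5,
    metric: str = "gt",
) -> FrocCurve:
    """FROC curve: sweep the ROI score threshold from max to min.

    At each threshold only ROIs scoring at least that much count as
    detections; matching and the pooled Sens/FPI are recomputed.  With a
    single distinct score the curve is a single point.
    """
    all_scores = sorted(
        {float(r.score) for rois in scored_rois for r in rois}, reverse=True
    )
    if not all_scores:
        results = [
            match([], g, s, overlap_min, metric)
            for g, s in zip(gts, image_shapes)
        ]
        sens, fpi = sens_fpi(results)
        return FrocCurve(points=[(fpi, sens)], thresholds=[float("inf")])
    points = []
    for thr in all_scores:
        results = []
        for rois, g, s in zip(scored_rois, gts, image_shapes):
            kept = [r for r in rois if r.score >= thr]
            results.append(match(kept, g, s, overlap_min, metric))
        sens, fpi = sens_fpi(results)
        points.append((fpi, sens))
    order = np.argsort([p[0] for p in points], kind="stable")
    return FrocCurve(
        points=[points[i] for i in order],
        thresholds=[all_scores[i] for i in order],
    )


def stage_report(provenances: list) -> pd.DataFrame:
    """Per-stage counts of patches and ROIs, split by true label.

    ``provenances`` is a list of labeled per-image StageProvenance
    objects (see the pipeline module).  Rows: total/positive/negative
    patches and ROIs; one count column and one percentage column per
    stage, percentages relative to the first (attention) stage.  Counts
    are non-increasing left to right by construction of the pipeline.
    """
    rows = [
        "total_patches", "positive_patches", "negative_patches",
        "total_rois", "positive_rois", "negative_rois",
    ]
    counts = {row: {s: 0 for s in STAGE_NAMES} for row in rows}
    for prov in provenances:
        for stage in STAGE_NAMES:
            srec = prov.stages.get(stage)
            if srec is None:
                continue
            pos_p = sum(1 for pid in srec["patch_ids"] if prov.patch_labels.get(pid))
            counts["total_patches"][stage] += len(srec["patch_ids"])
            counts["positive_patches"][stage] += pos_p
            counts["negative_patches"][stage] += len(srec["patch_ids"]) - pos_p
            groups = srec["roi_groups"]
            pos_r = sum(1 for gi, is_pos in enumerate(srec["roi_labels"]) if is_pos)
            counts["total_rois"][stage] += len(groups)
            counts["positive_rois"][stage] += pos_r
            counts["negative_rois"][stage] += len(groups) - pos_r
    data = {}
    for stage in STAGE_NAMES:
        data[stage] = [counts[row][stage] for row in rows]
        base = [max(counts[row][STAGE_NAMES[0]], 1) for row in rows]
        data[f"{stage}_pct"] = [
            100.0 * counts[row][stage] / b for row, b in zip(rows, base)
        ]
    return pd.DataFrame(data, index=rows)
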