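"""End-to-end detection pipeline and benchmark training/evaluation.

Stage order: breast segmentation -> (optional pectoral removal) ->
enhancement -> morphological attention -> visual patches -> densification
rule -> shape rule -> texture features -> ROI growing -> kernel-ELM
verification.  Every stage records which candidates survived, so a run
can be accounted for stage by stage, and an empty candidate set at any
point short-circuits to an empty but valid result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import attention, preprocess, semantic, verification
from .config import PipelineConfig
from .errors import EmptyBreastError, TrainingError
from .evaluation import froc, match, overlap_ratio, sens_fpi, stage_report
from .io import GroundTruthRegion, Mammogram
from .patches import PatchPartition, cluster_patches, initial_spacing
from .phantom import PhantomTruth
from .verification import (
    ROI,
    CrossValResult,
    ElmModel,
    crossval_10fold,
    elm_predict,
    extract_all_features,
    grow_rois,
)

STAGE_NAMES = ("attention", "densification", "shape", "texture")


@dataclass
class StageProvenance:
    """Which candidates survived each stage, plus truth labels when known.

    ``stages`` maps a stage name to ``{"patch_ids": [...],
    "roi_groups": [[...], ...], "roi_labels": [...]}``; the ROI groups of
    the rule stages are the connected components of the candidate set at
    that point, and at the texture stage the grown-and-accepted ROIs.
    ``patch_labels``/``roi_labels`` are filled by :func:`label_provenance`
    once ground truth is available.
    """

    stages: dict[str, dict] = field(default_factory=dict)
    patch_labels: dict[int, bool] = field(default_factory=dict)
    config: dict | None = None

    def record(self, stage: str, patch_ids, roi_groups) -> None:
        self.stages[stage] = {
            "patch_ids": sorted(int(i) for i in patch_ids),
            "roi_groups": [sorted(int(i) for i in g) for g in roi_groups],
            "roi_labels": [False] * len(roi_groups),
        }

    def counts(self) -> dict[str, tuple[int, int]]:
        """(n_patches, n_rois) per recorded stage, in pipeline order."""
        return {
            s: (len(rec["patch_ids"]), len(rec["roi_groups"]))
            for s, rec in self.stages.items()
        }

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "patch_labels": {str(k): v for k, v in self.patch_labels.items()},
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageProvenance":
        prov = cls(stages=d.get("stages", {}), config=d.get("config"))
        prov.patch_labels = {
            int(k): bool(v) for k, v in d.get("patch_labels", {}).items()
        }
        return prov


@dataclass
class DetectionResult:
    """Per-image output: final ROIs plus per-stage provenance."""

    image_id: str
    shape: tuple[int, int]
    rois: list[ROI]
    provenance: StageProvenance | None = None
    config: PipelineConfig | None = None
    partition: PatchPartition | None = None
    all_rois: list[ROI] | None = None  # grown ROIs before classification


def _connected_groups(partition: PatchPartition, ids: set[int]) -> list[list[int]]:
    """Connected components of a candidate id set under patch adjacency."""
    if not ids:
        return []
    adj = partition.adjacency()
    seen: set[int] = set()
    groups = []
    for start in sorted(ids):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            pid = stack.pop()
            comp.append(pid)
            for n in adj.get(pid, ()):
                if n in ids and n not in seen:
                    seen.add(n)
                    stack.append(n)
        groups.append(sorted(comp))
    return groups


def _restrict_groups(
    groups0: list[list[int]], surviving: set[int]
) -> list[list[int]]:
    """Attention-stage components restricted to surviving candidates.

    A suspicious region persists while any of its patches survives and
    never splits, so the per-stage region count is monotone by
    construction.
    """
    out = []
    for g in groups0:
        kept = sorted(set(g) & surviving)
        if kept:
            out.append(kept)
    return out


def detect(
    image: Mammogram,
    config: PipelineConfig | None = None,
    model: ElmModel | None = None,
) -> DetectionResult:
    """Run the full three-stage pipeline on one mammogram.

    Without a trained ``model`` the result contains the post-shape
    candidate ROIs (grown, unscored); with one, only ROIs the classifier
    accepts are returned as detections, every grown ROI remaining
    available in ``all_rois`` with its decision score.
    """
    config = config or PipelineConfig()
    prov = StageProvenance(config=config.to_dict())
    empty = DetectionResult(
        image_id=image.id, shape=image.shape, rois=[], provenance=prov,
        config=config,
    )

    try:
        breast = preprocess.segment_breast(image)
    except EmptyBreastError:
        for s in STAGE_NAMES:
            prov.record(s, [], [])
        return empty
    if config.pectoral_removal:
        breast = preprocess.remove_pectoral(image, breast)
    enhanced = (
        preprocess.enhance(
            image, breast, radius=config.enhance_radius,
            stretch=config.enhance_stretch,
        )
        if config.enhance_enabled
        else Mammogram(
            pixels=np.where(breast.mask, image.pixels, 0).astype(np.uint8),
            id=image.id,
            laterality=image.laterality,
        )
    )

    opened = attention.open_with_disk(
        enhanced.pixels,
        radius=config.opening_radius,
        use_reconstruction=config.use_reconstruction,
    )
    saliency = attention.salient_regions(
        opened, breast, config.attention_threshold
    )
    partition = cluster_patches(enhanced, saliency, breast, config)
    empty.partition = partition
    # texture rules and features describe the tissue itself, so they read
    # the original (breast-masked) intensities, not the enhanced ones:
    # top/bottom-hat enhancement amplifies noise and would bias the
    # homogeneity statistic.  A light denoise keeps distance-1 sensor
    # noise out of the co-occurrence statistics.
    img = np.where(breast.mask, image.pixels, 0).astype(np.float64)
    if config.texture_smooth_sigma > 0:
        img = ndi.gaussian_filter(img, config.texture_smooth_sigma)
        img = np.where(breast.mask, img, 0.0)

    groups0 = _connected_groups(partition, partition.U)
    prov.record("attention", partition.U, groups0)
    if not partition.U:
        for s in STAGE_NAMES[1:]:
            prov.record(s, [], [])
        return empty

    if config.densification_enabled:
        semantic.filter_densification(
            partition, img, config.t_dens, config.glcm_levels
        )
    prov.record(
        "densification", partition.U, _restrict_groups(groups0, partition.U)
    )

    if config.shape_enabled:
        semantic.filter_shape(partition, img, config.t_e)
    prov.record("shape", partition.U, _restrict_groups(groups0, partition.U))

    if not partition.U:
        prov.record("texture", [], [])
        return empty

    features = extract_all_features(partition, img, config.glcm_levels)
    spacing = initial_spacing(image.shape, config.k_clusters)
    rois = grow_rois(
        partition,
        features,
        tau=config.roi_tau,
        max_extent=config.roi_max_extent_spacings * spacing,
    )

    if model is not None:
        feats = np.stack([r.features for r in rois])
        labels, scores = elm_predict(model, feats)
        for roi, lab, sc in zip(rois, labels, scores):
            roi.score = float(sc)
            roi.label = "mass" if lab > 0 else "normal"
        accepted = [r for r in rois if r.label == "mass"]
    else:
        accepted = rois

    surviving = {pid for r in accepted for pid in r.patch_ids if pid in partition.U}
    prov.record("texture", sorted(surviving), _restrict_groups(groups0, surviving))
    return DetectionResult(
        image_id=image.id,
        shape=image.shape,
        rois=accepted,
        provenance=prov,
        config=config,
        partition=partition,
        all_rois=rois,
    )


# ---------------------------------------------------------------------------
# ground-truth labeling


def label_provenance(
    result: DetectionResult,
    gts: list[GroundTruthRegion],
    overlap_min: float = 0.5,
    metric: str = "gt",
) -> None:
    """Attach truth labels to a detection's provenance, in place.

    A patch is positive when at least half of its own area lies inside a
    ground-truth region (patches are much smaller than masses, so the
    region-level rule is applied to the patch's area).  A candidate
    group / ROI is positive under the standard 50%-overlap rule against
    any annotation.
    """
    prov = result.provenance
    part = result.partition
    if prov is None or part is None:
        return
    gt_masks = [g.to_mask(result.shape) for g in gts]
    for pid, patch in part.patches.items():
        rows, cols = patch.pixels[:, 0], patch.pixels[:, 1]
        pos = any(
            gm[rows, cols].sum() >= 0.5 * patch.area for gm in gt_masks
        )
        prov.patch_labels[pid] = bool(pos)
    for stage, rec in prov.stages.items():
        labels = []
        for group in rec["roi_groups"]:
            gmask = np.isin(part.label_image, group)
            pos = any(
                overlap_ratio(gmask, gm, metric) > overlap_min for gm in gt_masks
            )
            labels.append(bool(pos))
        rec["roi_labels"] = labels


# ---------------------------------------------------------------------------
# benchmark runs


@dataclass
class BenchmarkResult:
    """Everything a benchmark run produces."""

    detections: list[DetectionResult]
    truths: list[PhantomTruth]
    crossval: CrossValResult | None
    model: ElmModel | None
    sens: float
    fpi: float
    stage_metrics: dict[str, tuple[float, float]]  # stage -> (sens, fpi)
    froc_curve: object | None
    stage_table: object | None  # pandas DataFrame
    threshold: float = 0.0  # chosen FROC operating point


def _truth_regions(truth: PhantomTruth) -> list[GroundTruthRegion]:
    return [
        GroundTruthRegion(id=f"mass{i}", mask=m)
        for i, m in enumerate(truth.mass_masks)
    ]


def run_benchmark(
    dataset: list,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> BenchmarkResult:
    """Detect on every image, cross-validate the ELM, score the result.

    ``dataset`` is a list of (Mammogram, PhantomTruth) pairs.  The
    pipeline runs through ROI growing on each image; grown ROIs are
    labeled by the 50%-overlap rule, the kernel ELM is evaluated by
    stratified 10-fold cross-validation (each ROI scored by the model
    that did not see it), and the out-of-fold decisions define the final
    detections, Sens/FPI, the FROC curve and the per-stage table.
    """
    config = config or PipelineConfig()
    detections: list[DetectionResult] = []
    truths: list[PhantomTruth] = []
    all_feats, all_labels, roi_index = [], [], []
    for image, truth in dataset:
        det = detect(image, config)
        gts = _truth_regions(truth)
        label_provenance(det, gts, config.overlap_min, config.overlap_metric)
        gt_masks = [g.to_mask(det.shape) for g in gts]
        for j, roi in enumerate(det.all_rois or []):
            pos = any(
                overlap_ratio(roi.mask, gm, config.overlap_metric)
                > config.overlap_min
                for gm in gt_masks
            )
            roi.label = "mass" if pos else "normal"
            all_feats.append(roi.features)
            all_labels.append(1 if pos else 0)
            roi_index.append((len(detections), j))
        detections.append(det)
        truths.append(truth)

    cv = None
    model = None
    if all_feats and len(set(all_labels)) == 2:
        x = np.stack(all_feats)
        y = np.asarray(all_labels)
        try:
            cv = crossval_10fold(
                x, y, c=config.elm_c, gamma=config.elm_gamma, seed=seed
            )
        except TrainingError:
            cv = None
        if cv is not None:
            for (img_i, roi_j), sc in zip(roi_index, cv.scores):
                roi = detections[img_i].all_rois[roi_j]
                roi.score = float(sc)
        try:
            model = verification.elm_train(
                x, y, c=config.elm_c, gamma=config.elm_gamma
            )
        except TrainingError:
            model = None

    gts_all = [_truth_regions(t) for t in truths]
    shapes = [d.shape for d in detections]

    # operating point: detection performance is quoted as the best
    # sensitivity achievable within the FPI budget, read off the
    # cross-validated FROC curve (out-of-fold scores)
    threshold = 0.0
    curve = None
    if cv is not None:
        curve = froc(
            [det.all_rois or [] for det in detections],
            gts_all,
            shapes,
            config.overlap_min,
            config.overlap_metric,
        )
        eligible = [
            (sens_i, -fpi_i, thr)
            for (fpi_i, sens_i), thr in zip(curve.points, curve.thresholds)
            if fpi_i <= config.fpi_budget
        ]
        if eligible:
            threshold = max(eligible)[2]
        elif curve.points:
            threshold = curve.thresholds[0]

    final_rois = []
    for det in detections:
        if cv is None:
            final_rois.append(list(det.all_rois or []))
        else:
            final_rois.append(
                [r for r in (det.all_rois or []) if r.score >= threshold]
            )
    results = [
        match(rs, g, s, config.overlap_min, config.overlap_metric)
        for rs, g, s in zip(final_rois, gts_all, shapes)
    ]
    sens, fpi = sens_fpi(results)

    # texture-stage provenance: out-of-fold accepted ROIs
    for det, rois in zip(detections, final_rois):
        det.rois = rois
        if det.provenance is not None and det.partition is not None:
            surviving = {
                pid for r in rois for pid in r.patch_ids if pid in det.partition.U
            }
            groups0 = det.provenance.stages["attention"]["roi_groups"]
            det.provenance.record(
                "texture", sorted(surviving), _restrict_groups(groups0, surviving)
            )
    for det, gts in zip(detections, gts_all):
        label_provenance(det, gts, config.overlap_min, config.overlap_metric)

    stage_metrics = {}
    for stage in STAGE_NAMES[:3]:
        stage_results = []
        for det, g, s in zip(detections, gts_all, shapes):
            groups = det.provenance.stages[stage]["roi_groups"]
            rois = [
                ROI(
                    patch_ids=frozenset(gr),
                    mask=np.isin(det.partition.label_image, gr)
                    if det.partition is not None
                    else np.zeros(s, dtype=bool),
                    features=np.zeros(verification.N_FEATURES),
                )
                for gr in groups
            ]
            stage_results.append(
                match(rois, g, s, config.overlap_min, config.overlap_metric)
            )
        stage_metrics[stage] = sens_fpi(stage_results)
    stage_metrics["texture"] = (sens, fpi)

    table = stage_report([d.provenance for d in detections])
    return BenchmarkResult(
        detections=detections,
        truths=truths,
        crossval=cv,
        model=model,
        sens=sens,
        fpi=fpi,
        stage_metrics=stage_metrics,
        froc_curve=curve,
        stage_table=table,
        threshold=threshold,
    )


def train(
    dataset: list,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[ElmModel, BenchmarkResult]:
    """Train a final kernel ELM on a labeled benchmark.

    Runs :func:`run_benchmark` for the cross-validated report and
    returns the model fitted on all ROIs together with that report.
    Raises :class:`TrainingError` when the dataset yields no positive
    ROI.
    """
    result = run_benchmark(dataset, config, seed)
    if result.model is None:
        raise TrainingError(
            "benchmark produced no trainable ROI set (need both classes)"
        )
    return result.model, result
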