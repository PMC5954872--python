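"""Stage-3 verification: texture features, ROI growing, kernel ELM.

Each candidate patch is described by 12 texture features (two first-order
statistics plus ten derived from the patch's gray-level co-occurrence
matrix and intensity histogram).  Surviving candidates seed a region
growing that merges neighbouring patches with similar texture into ROIs,
whose feature vector is the arithmetic mean of the member patches'.  A
kernel extreme learning machine — a single-hidden-layer feedforward
network whose output weights have the closed form
beta = (I/C + Omega)^-1 t with Omega the RBF kernel matrix — finally
separates mass from normal ROIs.  The kernel variant has no random
hidden layer, so training is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold

from .errors import TrainingError
from .patches import PatchPartition, VisualPatch
from .semantic import glcm, glcm_correlation

FEATURE_NAMES = (
    "gray_mean",
    "gray_variance",
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "standard_deviation",
    "inverse_difference_moment",
    "kurtosis",
    "skewness",
    "entropy",
    "root_mean_square",
)
N_FEATURES = len(FEATURE_NAMES)


@dataclass
class ROI:
    """A region of interest: adjacent patches merged by region growing."""

    patch_ids: frozenset[int]
    mask: np.ndarray
    features: np.ndarray
    score: float = 0.0
    label: str = "unlabeled"  # mass | normal | unlabeled

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class ElmModel:
    """Kernel extreme learning machine (binary, targets +-1)."""

    kernel: str
    gamma: float
    c: float
    support: np.ndarray  # standardized training features
    beta: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "gamma": self.gamma,
            "c": self.c,
            "support": self.support.tolist(),
            "beta": self.beta.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElmModel":
        return cls(
            kernel=d["kernel"],
            gamma=float(d["gamma"]),
            c=float(d["c"]),
            support=np.asarray(d["support"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_scale=np.asarray(d["feature_scale"], dtype=float),
        )


# ---------------------------------------------------------------------------
# features


def extract_features(
    patch: VisualPatch,
    image: np.ndarray,
    levels: int = 16,
) -> np.ndarray:
    """12-feature texture vector of one patch (order: FEATURE_NAMES).

    Gray mean/variance and the histogram statistics (kurtosis, skewness,
    entropy, RMS) are computed on the raw patch intensities; contrast,
    correlation, energy, homogeneity, standard deviation and inverse
    difference moment come from the patch's co-occurrence matrix.  A
    constant patch yields variance 0, energy 1 and entropy 0.
    """
    image = np.asarray(image, dtype=np.float64)
    vals = image[patch.pixels[:, 0], patch.pixels[:, 1]]
    mean = float(vals.mean())
    var = float(vals.var())

    m = glcm(patch, image, levels).matrix
    i = np.arange(levels, dtype=np.float64)[:, None]
    j = np.arange(levels, dtype=np.float64)[None, :]
    contrast = float(((i - j) ** 2 * m).sum())
    correlation = glcm_correlation(m)
    energy = float((m**2).sum())
    homogeneity = float((m / (1.0 + np.abs(i - j))).sum())
    u_i = float((i * m).sum())
    u_j = float((j * m).sum())
    var_i = float(((i - u_i) ** 2 * m).sum())
    var_j = float(((j - u_j) ** 2 * m).sum())
    glcm_std = float(np.sqrt((var_i + var_j) / 2.0))
    idm = float((m / (1.0 + (i - j) ** 2)).sum())

    if var > 0:
        kurt = float(sstats.kurtosis(vals, fisher=True, bias=True))
        skew = float(sstats.skew(vals, bias=True))
    else:
        kurt = 0.0
        skew = 0.0
    hist = np.bincount(np.rint(vals).astype(int), minlength=256)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum())
    rms = float(np.sqrt((vals**2).mean()))

    return np.array(
        [mean, var, contrast, correlation, energy, homogeneity,
         glcm_std, idm, kurt, skew, entropy, rms],
        dtype=np.float64,
    )


def extract_all_features(
    partition: PatchPartition, image: np.ndarray, levels: int = 16
) -> dict[int, np.ndarray]:
    return {
        pid: extract_features(p, image, levels)
        for pid, p in partition.patches.items()
    }


# ---------------------------------------------------------------------------
# region growing


def grow_rois(
    partition: PatchPartition,
    features: dict[int, np.ndarray],
    tau: float = 2.5,
    max_extent: float | None = None,
) -> list[ROI]:
    """Grow ROIs from the candidate patches left in U.

    Each unvisited candidate seeds an ROI.  Neighbouring patches (sharing
    a boundary in the label image) join when their standardized feature
    Euclidean distance to the ROI's running mean is at most ``tau``,
    nearest first, iterating until no neighbour qualifies.  An ROI is the
    local neighbourhood of its focal seed, so growth is confined to
    patches whose centroid lies within ``max_extent`` pixels of the seed
    centroid (no cap when ``None``); this keeps a loose ``tau`` from
    flooding homogeneous background.  Growth may absorb non-candidate
    patches — the seeds carry the detection decision, the grown extent
    delineates it.  The final ROI feature vector is the arithmetic mean
    of the member patches' raw feature vectors.
    """
    if not partition.U:
        return []
    ids = sorted(features)
    mat = np.stack([features[i] for i in ids])
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale[scale == 0] = 1.0
    z = {pid: (features[pid] - mean) / scale for pid in ids}

    adj = partition.adjacency()
    assigned: set[int] = set()
    rois: list[ROI] = []
    for seed in sorted(partition.U):
        if seed in assigned:
            continue
        seed_centroid = np.asarray(partition.patches[seed].centroid)
        members = [seed]
        assigned.add(seed)
        running = z[seed].copy()
        while True:
            frontier = sorted(
                {
                    n
                    for pid in members
                    for n in adj.get(pid, ())
                    if n not in assigned and n in z
                }
            )
            best = None
            best_d = tau
            for n in frontier:
                if max_extent is not None:
                    c = np.asarray(partition.patches[n].centroid)
                    if float(np.linalg.norm(c - seed_centroid)) > max_extent:
                        continue
                d = float(np.linalg.norm(z[n] - running))
                if d <= best_d:
                    best, best_d = n, d
            if best is None:
                break
            members.append(best)
            assigned.add(best)
            running = np.mean([z[pid] for pid in members], axis=0)
        mask = np.isin(partition.label_image, members)
        feats = np.mean([features[pid] for pid in members], axis=0)
        rois.append(
            ROI(patch_ids=frozenset(members), mask=mask, features=feats)
        )
    return rois


# ---------------------------------------------------------------------------
# kernel extreme learning machine


def _standardize_fit(x: np.ndarray):
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def elm_train(
    x: np.ndarray,
    y: np.ndarray,
    c: float = 10.0,
    gamma: float = 0.01,
) -> ElmModel:
    """Train a kernel ELM: beta = (I/C + Omega)^-1 t, Omega = RBF kernel.

    ``y`` holds two classes (any labels); they are mapped to targets -1
    and +1 in sorted order.  Features are standardized and the
    standardization is stored with the model.  Training is deterministic.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise TrainingError(f"need exactly 2 classes, got {classes.size}")
    if min((y == cls).sum() for cls in classes) < 2:
        raise TrainingError("need >= 2 examples per class")
    t = np.where(y == classes[1], 1.0, -1.0)
    mean, scale = _standardize_fit(x)
    xs = (x - mean) / scale
    omega = rbf_kernel(xs, xs, gamma=gamma)
    n = len(xs)
    beta = np.linalg.solve(np.eye(n) / c + omega, t)
    return ElmModel(
        kernel="rbf",
        gamma=gamma,
        c=c,
        support=xs,
        beta=beta,
        feature_mean=mean,
        feature_scale=scale,
    )


def elm_decision(model: ElmModel, x: np.ndarray) -> np.ndarray:
    """Real-valued scores k(x, support) @ beta (positive = mass)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    xs = (x - model.feature_mean) / model.feature_scale
    return rbf_kernel(xs, model.support, gamma=model.gamma) @ model.beta


def elm_predict(model: ElmModel, x: np.ndarray):
    """Labels (+1/-1) and scores; the label is the sign of the score."""
    scores = elm_decision(model, x)
    labels = np.where(scores > 0, 1, -1)
    return labels, scores


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValResult:
    """Pooled out-of-fold predictions for a labeled ROI set."""

    n_folds: int
    fold_of: np.ndarray  # fold index per example
    scores: np.ndarray  # out-of-fold decision values, input order
    predicted: np.ndarray  # out-of-fold +-1 labels
    targets: np.ndarray  # +-1 ground truth
    confusion: dict[str, int] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float((self.predicted == self.targets).mean())


def crossval_10fold(
    x: np.ndarray,
    y: np.ndarray,
    c: float = 10.0,
    gamma: float = 0.01,
    seed: int = 0,
    n_folds: int = 10,
) -> CrossValResult:
    """Stratified k-fold CV of the kernel ELM with pooled predictions.

    When the minority class has fewer members than ``n_folds`` the fold
    count is reduced (with a warning) so every fold sees both classes.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise TrainingError(f"need exactly 2 classes, got {classes.size}")
    t = np.where(y == classes[1], 1, -1)
    min_class = min(int((t == v).sum()) for v in (-1, 1))
    if min_class < 4:
        raise TrainingError(
            f"minority class has {min_class} members; need >= 4 for "
            "stratified cross-validation"
        )
    folds = min(n_folds, min_class)
    if folds < n_folds:
        warnings.warn(
            f"minority class has {min_class} members; using {folds} folds",
            stacklevel=2,
        )
    if folds < 2:
        raise TrainingError("need >= 2 members per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(x))
    predicted = np.zeros(len(x), dtype=int)
    fold_of = np.zeros(len(x), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(x, t)):
        model = elm_train(x[train_idx], t[train_idx], c=c, gamma=gamma)
        lab, sc = elm_predict(model, x[test_idx])
        scores[test_idx] = sc
        predicted[test_idx] = lab
        fold_of[test_idx] = fold
    confusion = {
        "tp": int(((predicted == 1) & (t == 1)).sum()),
        "fp": int(((predicted == 1) & (t == -1)).sum()),
        "fn": int(((predicted == -1) & (t == 1)).sum()),
        "tn": int(((predicted == -1) & (t == -1)).sum()),
    }
    return CrossValResult(
        n_folds=folds,
        fold_of=fold_of,
        scores=scores,
        predicted=predicted,
        targets=t,
        confusion=confusion,
    )
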