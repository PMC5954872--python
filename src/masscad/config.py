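"""Pipeline configuration.

All tunable thresholds of the three detection stages live in one dataclass
so that a run can be reproduced from a single YAML snapshot.  The defaults
are the operating point used throughout the package: attention threshold
0.5, densification threshold 0.93, shape (eccentricity) threshold 0.86,
K = 2000 cluster centers, spatial balance S = 25, opening radius 6 px,
and a kernel extreme learning machine with C = 10 and an RBF kernel of
width 0.01.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

_KERNELS = ("rbf",)


@dataclass
class PipelineConfig:
    """Thresholds and hyperparameters for one end-to-end detection run.

    Parameters
    ----------
    attention_threshold:
        Minimum normalized peak intensity (peak/255) a regional-maxima
        component must reach to count as salient.  Range [0, 1].
    t_dens:
        Densification (GLCM-correlation) threshold; candidate patches
        below it are rejected as normal tissue.  Range [0, 1].
    t_e:
        Eccentricity threshold; patches whose fitted-ellipse eccentricity
        is >= t_e are rejected as elongated (glandular) tissue.
    k_clusters:
        Number of initial cluster centers for visual-patch generation.
    compactness_mu:
        Pixel-compactness weight mu of the patch similarity index.
    balance_s:
        Constant S balancing spatial proximity against gray distance.
    opening_radius:
        Radius (px) of the flat disk structuring element used by the
        attention stage's morphological opening.
    enhance_radius:
        Radius (px) of the disk used by top-hat/bottom-hat enhancement.
    elm_c, elm_kernel, elm_gamma:
        Kernel extreme-learning-machine trade-off constant, kernel type
        and RBF width.
    glcm_levels:
        Gray-level quantization used for per-patch co-occurrence matrices.
    texture_smooth_sigma:
        Gaussian denoising width (px) applied to the intensity image
        before any co-occurrence/texture computation; 0 disables.  The
        correlation statistic compares distance-1 neighbours, so
        unsmoothed sensor noise would dominate it.
    roi_tau:
        Region-growing threshold: maximum standardized feature distance
        between a neighbouring patch and the running ROI mean.
    roi_max_extent_spacings:
        Spatial cap on ROI growth, in multiples of the initial patch
        spacing sqrt(H*W/K), measured seed centroid to patch centroid.
    overlap_min:
        Minimum overlap ratio for a detection to count as a true positive.
    overlap_metric:
        ``"gt"`` divides the intersection by the ground-truth area,
        ``"iou"`` by the union.
    fpi_budget:
        False positives per image allowed when picking the reporting
        operating point on the cross-validated FROC curve (detection
        performance is conventionally quoted as the best sensitivity at
        ~2 FP/image).
    use_reconstruction:
        If true, the attention stage uses opening-by-reconstruction
        instead of plain opening.
    pectoral_removal:
        If true, a pectoral wedge is excised before enhancement.
    enhance_enabled, densification_enabled, shape_enabled:
        Independent switches for the preprocessing enhancement and the
        two semantic rules, for stagewise ablations.
    patch_iterations:
        Fixed number of assignment/update sweeps in patch clustering.
    """

    attention_threshold: float = 0.5
    t_dens: float = 0.93
    t_e: float = 0.86
    k_clusters: int = 2000
    compactness_mu: float = 50.0
    balance_s: float = 25.0
    opening_radius: int = 6
    enhance_radius: int = 30
    elm_c: float = 10.0
    elm_kernel: str = "rbf"
    elm_gamma: float = 0.01
    glcm_levels: int = 16
    texture_smooth_sigma: float = 1.0
    roi_tau: float = 2.5
    roi_max_extent_spacings: float = 1.8
    overlap_min: float = 0.5
    overlap_metric: str = "gt"
    fpi_budget: float = 2.0
    use_reconstruction: bool = True
    pectoral_removal: bool = False
    enhance_enabled: bool = True
    enhance_stretch: bool = True
    densification_enabled: bool = True
    shape_enabled: bool = True
    patch_iterations: int = 10

    def __post_init__(self) -> None:
        for name in ("attention_threshold", "t_dens", "t_e", "overlap_min"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigError(f"{name}={v!r} outside [0, 1]")
        if self.k_clusters < 4:
            raise ConfigError(f"k_clusters={self.k_clusters} < 4")
        if self.compactness_mu <= 0 or self.balance_s <= 0:
            raise ConfigError("compactness_mu and balance_s must be positive")
        if self.opening_radius < 1:
            raise ConfigError(f"opening_radius={self.opening_radius} < 1")
        if self.enhance_radius < 1:
            raise ConfigError(f"enhance_radius={self.enhance_radius} < 1")
        if self.elm_c <= 0 or self.elm_gamma <= 0:
            raise ConfigError("elm_c and elm_gamma must be positive")
        if self.elm_kernel not in _KERNELS:
            raise ConfigError(f"elm_kernel={self.elm_kernel!r} not in {_KERNELS}")
        if self.glcm_levels < 2:
            raise ConfigError(f"glcm_levels={self.glcm_levels} < 2")
        if self.texture_smooth_sigma < 0:
            raise ConfigError("texture_smooth_sigma must be >= 0")
        if self.roi_tau <= 0:
            raise ConfigError("roi_tau must be positive")
        if self.roi_max_extent_spacings <= 0:
            raise ConfigError("roi_max_extent_spacings must be positive")
        if self.overlap_metric not in ("gt", "iou"):
            raise ConfigError(f"overlap_metric={self.overlap_metric!r}")
        if self.fpi_budget <= 0:
            raise ConfigError("fpi_budget must be positive")
        if self.patch_iterations < 1:
            raise ConfigError("patch_iterations must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


#: initial patch area implied by the reference operating point
#: (1024 x 1024 image, K = 2000): H*W/K pixels per patch.
REFERENCE_PATCH_AREA = 1024 * 1024 / 2000


def config_for_image_size(
    shape: tuple[int, int], base: PipelineConfig | None = None
) -> PipelineConfig:
    """Scale the cluster count so patches keep their reference size.

    The initial patch area is H*W/K; the rule thresholds were set for
    ~524-px patches (1024 x 1024, K = 2000), and the homogeneity
    statistic depends on the patch scale, so detection on smaller images
    keeps the patch area constant by scaling K down, not the patches.
    """
    base = base or PipelineConfig()
    k = max(4, round(shape[0] * shape[1] / REFERENCE_PATCH_AREA))
    return base.replace(k_clusters=k)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a config from YAML; a missing path yields all defaults.

    Keys absent from the file keep their default; unknown keys or
    out-of-range values raise :class:`ConfigError`.
    """
    if path is None:
        return PipelineConfig()
    p = Path(path)
    if not p.exists():
        return PipelineConfig()
    with open(p) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{p}: config file must contain a mapping")
    return PipelineConfig.from_dict({**PipelineConfig().to_dict(), **data})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
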