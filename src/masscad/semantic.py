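"""Stage-2 semantic integration: densification and shape rules.

Two morphological observations separate masses from normal tissue:

* a mass is a focal, self-similar densification of the parenchyma, so
  its visual patches are homogeneous — measured here as the correlation
  statistic of the patch's gray-level co-occurrence matrix (GLCM);
* masses tend to be round or oval, while glandular tissue forms
  elongated strips — measured as the eccentricity of an ellipse fitted
  by least squares to the patch boundary.

Candidate patches failing either rule move from the candidate set U to
the normal set N.  Both rules only ever shrink U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import DegenerateShapeError
from .patches import PatchPartition, VisualPatch

#: 4-direction symmetric offset set used for orientation-averaged
#: texture features
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
#: unit-distance offsets used by the densification rule: the correlation
#: statistic compares neighbours at distance 1, and mixing in the
#: sqrt(2)-distant diagonal pairs systematically deflates it on smooth
#: tissue
AXIAL_OFFSETS = ((0, 1), (1, 0))


@dataclass
class GlcmMatrix:
    """Normalized symmetric gray-level co-occurrence matrix of one patch."""

    matrix: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool = True


@dataclass
class EllipseFit:
    """A conic fitted to boundary points, reduced to semi-axes a >= b."""

    conic: tuple[float, float, float, float, float, float]
    semi_major: float
    semi_minor: float
    eccentricity: float
    valid: bool


# ---------------------------------------------------------------------------
# GLCM and densification


def _quantize(
    values: np.ndarray, levels: int, value_range: tuple[float, float] | None
) -> np.ndarray:
    """Quantize intensities to ``levels`` bins.

    ``value_range`` gives the gray range the bins span (the declared
    8-bit range by default); ``None`` uses the values' own min-max.
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = value_range if value_range is not None else (values.min(), values.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm(
    patch: VisualPatch,
    image: np.ndarray,
    levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    value_range: tuple[float, float] | None = None,
) -> GlcmMatrix:
    """Co-occurrence matrix of a patch's own pixels.

    Intensities are quantized to ``levels`` bins over the patch's own
    min-max range by default (``value_range`` can pin a fixed range such
    as (0, 255) instead).  Pairs are counted only when
    both pixels belong to the patch, accumulated symmetrically over all
    ``offsets``, and normalized to sum to one.  A patch with no valid
    pair (tiny or scattered) degenerates to all mass in the (0, 0) cell.
    """
    image = np.asarray(image, dtype=np.float64)
    rows, cols = patch.pixels[:, 0], patch.pixels[:, 1]
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    box = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=np.int64)
    inside = np.zeros_like(box, dtype=bool)
    vals = image[rows, cols]
    box[rows - r0, cols - c0] = _quantize(vals, levels, value_range)
    inside[rows - r0, cols - c0] = True

    m = np.zeros((levels, levels), dtype=np.float64)
    h, w = box.shape
    for dr, dc in offsets:
        sr0, sr1 = max(0, -dr), min(h, h - dr)
        sc0, sc1 = max(0, -dc), min(w, w - dc)
        a = box[sr0:sr1, sc0:sc1]
        b = box[sr0 + dr : sr1 + dr, sc0 + dc : sc1 + dc]
        ok = inside[sr0:sr1, sc0:sc1] & inside[sr0 + dr : sr1 + dr, sc0 + dc : sc1 + dc]
        np.add.at(m, (a[ok], b[ok]), 1.0)
        np.add.at(m, (b[ok], a[ok]), 1.0)
    total = m.sum()
    if total == 0:
        m[0, 0] = 1.0
    else:
        m /= total
    return GlcmMatrix(matrix=m, levels=levels, offsets=tuple(offsets))


def glcm_correlation(m: np.ndarray) -> float:
    """Correlation statistic of a normalized co-occurrence matrix.

    With marginal means u_i, u_j and standard deviations s_i, s_j,
    corr = (sum_ij i*j*M(i,j) - u_i*u_j) / (s_i*s_j), in [-1, 1].
    A zero-variance (single-level) matrix returns 1 by convention:
    a perfectly uniform patch is perfectly homogeneous.
    """
    levels = m.shape[0]
    i = np.arange(levels, dtype=np.float64)[:, None]
    j = np.arange(levels, dtype=np.float64)[None, :]
    u_i = float((i * m).sum())
    u_j = float((j * m).sum())
    var_i = float(((i - u_i) ** 2 * m).sum())
    var_j = float(((j - u_j) ** 2 * m).sum())
    if var_i <= 0 or var_j <= 0:
        return 1.0
    cov = float((i * j * m).sum()) - u_i * u_j
    return cov / np.sqrt(var_i * var_j)


def densification(
    patch: VisualPatch,
    image: np.ndarray,
    levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = AXIAL_OFFSETS,
    value_range: tuple[float, float] | None = None,
) -> float:
    """Densification of a patch: the correlation of its GLCM.

    High values mean the patch is a smooth, self-similar densification
    (mass-like); textured normal tissue scores lower.  Although the
    statistic formally ranges over [-1, 1], mammographic patches sit in
    the upper part of the range; a constant patch returns exactly 1.
    """
    return glcm_correlation(glcm(patch, image, levels, offsets, value_range).matrix)


def filter_densification(
    partition: PatchPartition,
    image: np.ndarray,
    t_dens: float = 0.93,
    levels: int = 16,
) -> PatchPartition:
    """Move candidates with densification below ``t_dens`` from U to N."""
    dens_stats = partition.stats.setdefault("densification", {})
    for pid in sorted(partition.U):
        d = densification(partition.patches[pid], image, levels)
        dens_stats[pid] = d
        if d < t_dens:
            partition.move_to_N(pid)
    return partition


# ---------------------------------------------------------------------------
# ellipse fitting and the shape rule


def fit_ellipse(edge_points: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit to boundary points.

    Fits the conic A'x^2 + B'xy + C'y^2 + D'x + E'y + F' = 0 with the
    ellipse constraint B'^2 - 4A'C' < 0 built into the eigenproblem
    (Fitzgibbon's direct method), then recovers the semi-axes from the
    eigen-decomposition of the quadratic part.  Points are (row, col);
    internally x = col, y = row.  Fewer than 6 points, collinear points
    or a failed solve raise :class:`DegenerateShapeError`.
    """
    pts = np.asarray(edge_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 6:
        raise DegenerateShapeError(f"need >= 6 edge points, got {pts.shape[0]}")
    x = pts[:, 1]
    y = pts[:, 0]
    # center and scale for conditioning
    mx, my = x.mean(), y.mean()
    sx = max(np.abs(x - mx).max(), 1e-12)
    sy = max(np.abs(y - my).max(), 1e-12)
    if np.linalg.matrix_rank(np.stack([x - mx, y - my], axis=1), tol=1e-9) < 2:
        raise DegenerateShapeError("collinear edge points")
    xs, ys = (x - mx) / sx, (y - my) / sy

    d1 = np.stack([xs**2, xs * ys, ys**2], axis=1)
    d2 = np.stack([xs, ys, np.ones_like(xs)], axis=1)
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError("singular scatter matrix") from exc
    m = s1 + s2 @ t
    c1_inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    try:
        eigval, eigvec = np.linalg.eig(c1_inv @ m)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError("eigen-solve failed") from exc
    eigval = np.real(eigval)
    eigvec = np.real(eigvec)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.flatnonzero((cond > 0) & np.isfinite(eigval))
    if good.size == 0:
        raise DegenerateShapeError("no ellipse solution")
    a1 = eigvec[:, good[0]]
    a2 = t @ a1
    # undo the normalization: coefficients in original (x, y)
    A = a1[0] / sx**2
    B = a1[1] / (sx * sy)
    C = a1[2] / sy**2
    D = a2[0] / sx - 2 * a1[0] * mx / sx**2 - a1[1] * my / (sx * sy)
    E = a2[1] / sy - 2 * a1[2] * my / sy**2 - a1[1] * mx / (sx * sy)
    F = (
        a2[2]
        + a1[0] * mx**2 / sx**2
        + a1[2] * my**2 / sy**2
        + a1[1] * mx * my / (sx * sy)
        - a2[0] * mx / sx
        - a2[1] * my / sy
    )
    return _conic_to_ellipse((A, B, C, D, E, F))


def _conic_to_ellipse(conic: tuple[float, ...]) -> EllipseFit:
    """Semi-axes of a conic via eigen-decomposition of its quadratic part."""
    A, B, C, D, E, F = conic
    if A + C < 0:  # normalize overall sign so an ellipse has A, C > 0
        A, B, C, D, E, F = (-A, -B, -C, -D, -E, -F)
        conic = (A, B, C, D, E, F)
    q = np.array([[A, B / 2], [B / 2, C]])
    qq = np.array([[A, B / 2, D / 2], [B / 2, C, E / 2], [D / 2, E / 2, F]])
    det_q = np.linalg.det(q)
    if det_q <= 0:
        return EllipseFit(conic=conic, semi_major=0.0, semi_minor=0.0,
                          eccentricity=1.0, valid=False)
    k = -np.linalg.det(qq) / det_q
    lam = np.linalg.eigvalsh(q)
    if k <= 0 or lam[0] <= 0:
        return EllipseFit(conic=conic, semi_major=0.0, semi_minor=0.0,
                          eccentricity=1.0, valid=False)
    axes = np.sqrt(k / lam)  # lam ascending -> axes descending
    a, b = float(axes[0]), float(axes[1])
    ecc = float(np.sqrt(max(0.0, 1.0 - (b / a) ** 2)))
    return EllipseFit(conic=conic, semi_major=a, semi_minor=b,
                      eccentricity=ecc, valid=True)


def eccentricity(fit: EllipseFit) -> float:
    """E = sqrt(1 - (b/a)^2); 0 for a circle, -> 1 as the ellipse flattens."""
    if not fit.valid:
        return 1.0
    return fit.eccentricity


def patch_eccentricity(
    patch: VisualPatch, label_image: np.ndarray
) -> float:
    """Eccentricity of the ellipse fitted to a patch's boundary.

    Degenerate boundaries (too few or collinear points, no ellipse
    solution) are treated as maximally eccentric (E = 1).
    """
    try:
        fit = fit_ellipse(patch.edge_points(label_image))
    except DegenerateShapeError:
        return 1.0
    return eccentricity(fit)


def filter_shape(
    partition: PatchPartition,
    image: np.ndarray | None = None,
    t_e: float = 0.86,
) -> PatchPartition:
    """Move candidates with eccentricity >= ``t_e`` from U to N.

    The boundary test uses >=: a patch exactly at the threshold is
    rejected.  ``image`` is accepted for interface symmetry with the
    densification filter but the rule only needs patch geometry.
    """
    ecc_stats = partition.stats.setdefault("eccentricity", {})
    for pid in sorted(partition.U):
        e = patch_eccentricity(partition.patches[pid], partition.label_image)
        ecc_stats[pid] = e
        if e >= t_e:
            partition.move_to_N(pid)
    return partition
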