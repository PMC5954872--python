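"""Synthetic mammographic phantoms with exact ground truth.

The generator renders the structures the detection rules key on, at desk
scale (256 x 256 by default):

* a bright breast half-disk on a dark background, base intensity set by
  a density level analogous to the fatty (F) / fatty-glandular (G) /
  dense-glandular (D) classes;
* an optional pectoral-muscle wedge in the top chest-wall corner;
* glandular strips radiating from the nipple like a crown, rendered as
  Gaussian-profile ridges carrying a coarse fibrous texture (so they are
  elongated AND inhomogeneous — the two properties the semantic rules
  reject);
* round/oval masses with a smooth dome profile (axis ratio sampled in
  [1.0, 1.6]) that locally displace the glandular pattern, as a growing
  mass disrupts normal parenchyma;
* an optional bright label artifact outside the breast;
* additive Gaussian noise followed by a mild acquisition blur, giving
  the spatially correlated film-grain noise of digitized film.

Every mask of every layer is returned as ground truth, so each pipeline
stage can be scored against what was actually rendered.  All randomness
flows through one seeded generator; the same spec yields byte-identical
images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .errors import PlacementError
from .io import GroundTruthRegion, Mammogram, write_annotations, write_mammogram

DENSITY_BASE = {"F": 90.0, "G": 110.0, "D": 130.0}
BACKGROUND = 5.0
PECTORAL_CONTRAST = 40.0

# tissue label codes in PhantomTruth.tissue_labels
TISSUE_BG = 0
TISSUE_BASE = 1
TISSUE_GLAND = 2
TISSUE_PECTORAL = 3
TISSUE_MASS = 4


@dataclass
class PhantomSpec:
    """Parameters of one phantom; ``seed`` is mandatory.

    ``mass_radius_range`` bounds the semi-major axis in pixels and
    ``mass_contrast_range`` the peak contrast in gray levels over the
    base tissue.  ``density_level`` sets the base intensity (F 90,
    G 110, D 130).  ``noise_sigma`` is the additive Gaussian noise
    before the acquisition blur of width ``blur_sigma``.
    ``mottle_sigma``/``mottle_scale`` set the amplitude (gray levels)
    and correlation length (px) of the smooth zero-mean parenchymal
    mottle across the breast — the large-scale texture that makes every
    real-mammogram patch locally smooth.
    """

    seed: int
    size: tuple[int, int] = (256, 256)
    laterality: str = "left"
    n_masses: int = 1
    mass_radius_range: tuple[float, float] = (24.0, 48.0)
    mass_contrast_range: tuple[float, float] = (20.0, 60.0)
    density_level: str = "G"
    n_gland_strips: int = 12
    pectoral: bool = False
    noise_sigma: float = 1.5
    blur_sigma: float = 0.8
    mottle_sigma: float = 4.0
    mottle_scale: float = 10.0
    label_artifact: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("PhantomSpec.seed is mandatory")
        if self.density_level not in DENSITY_BASE:
            raise ValueError(f"density_level must be one of {set(DENSITY_BASE)}")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")


@dataclass
class PhantomTruth:
    """Generative ground truth aligned to the rendered image."""

    breast_mask: np.ndarray
    pectoral_mask: np.ndarray
    gland_mask: np.ndarray
    mass_masks: list[np.ndarray]
    mass_regions: list[GroundTruthRegion]
    tissue_labels: np.ndarray
    density_level: str = "G"


def _breast_geometry(spec: PhantomSpec):
    h, w = spec.size
    radius = 0.46 * min(h, w)
    center_col = 0.0 if spec.laterality == "left" else w - 1.0
    center = (h / 2.0, center_col)
    return center, radius


def _render_glands(spec: PhantomSpec, rng, breast_mask, center, radius):
    """Gaussian-profile ridges radiating from the nipple, with fibrous texture."""
    h, w = spec.size
    layer = np.zeros((h, w))
    sign = 1.0 if spec.laterality == "left" else -1.0
    nipple = (center[0], center[1] + sign * radius * 0.95)
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(spec.n_gland_strips):
        # direction from the nipple back toward the chest wall
        u = rng.uniform(-0.95, 0.95)
        theta = math.pi + u if spec.laterality == "left" else u
        dr = math.sin(theta)
        dc = math.cos(theta)
        length = rng.uniform(0.35, 0.80) * radius
        start = rng.uniform(0.05, 0.25) * radius
        width = rng.uniform(4.0, 10.0)
        amp = rng.uniform(10.0, 35.0)
        p0 = np.array([nipple[0] + dr * start, nipple[1] + dc * start])
        p1 = np.array([nipple[0] + dr * (start + length), nipple[1] + dc * (start + length)])
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        if seg_len2 == 0:
            continue
        t = ((rr - p0[0]) * seg[0] + (cc - p0[1]) * seg[1]) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        pr = p0[0] + t * seg[0]
        pc = p0[1] + t * seg[1]
        d2 = (rr - pr) ** 2 + (cc - pc) ** 2
        ridge = amp * np.exp(-d2 / (2.0 * (width / 2.0) ** 2))
        # taper toward the far end
        ridge *= 1.0 - 0.4 * t
        layer = np.maximum(layer, ridge)
    gland_mask = (layer > 5.0) & breast_mask
    # coarse fibrous texture: 3-px blocks of +-, confined to the glands
    block = 3
    coarse = rng.normal(0.0, 1.0, (h // block + 1, w // block + 1))
    texture = np.kron(coarse, np.ones((block, block)))[:h, :w]
    layer = layer + 6.0 * texture * gland_mask
    return np.where(breast_mask, layer, 0.0), gland_mask


def _place_masses(spec: PhantomSpec, rng, center, radius, pectoral_mask):
    """Rejection-sample non-overlapping mass geometries inside the breast."""
    h, w = spec.size
    sign = 1.0 if spec.laterality == "left" else -1.0
    placed = []
    lo, hi = spec.mass_radius_range
    if spec.n_masses >= 2:
        # multiple lesions must share the breast; keep them in the lower
        # half of the size range so placement stays feasible
        hi = lo + 0.5 * (hi - lo)
    for _ in range(spec.n_masses):
        ok = False
        for _try in range(400):
            a = rng.uniform(lo, hi)
            ratio = rng.uniform(1.0, 1.6)
            b = a / ratio
            phi = rng.uniform(0.0, math.pi)
            contrast = rng.uniform(*spec.mass_contrast_range)
            rad_pos = rng.uniform(0.25, 0.80) * radius
            ang = rng.uniform(-0.9, 0.9)
            r0 = center[0] + rad_pos * math.sin(ang)
            c0 = center[1] + sign * rad_pos * math.cos(ang)
            # fully inside the breast disk with margin
            if math.hypot(r0 - center[0], c0 - center[1]) + a > radius - 3:
                continue
            ri, ci = int(round(r0)), int(round(c0))
            if not (0 <= ri < h and 0 <= ci < w):
                continue
            if pectoral_mask[ri, ci]:
                continue
            if any(
                math.hypot(r0 - m["r0"], c0 - m["c0"]) < a + m["a"] + 4
                for m in placed
            ):
                continue
            placed.append(
                {"r0": r0, "c0": c0, "a": a, "b": b, "phi": phi, "contrast": contrast}
            )
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place mass {len(placed) + 1} of {spec.n_masses} "
                "after 400 tries"
            )
    return placed


def _mass_profile(geom, shape):
    """Smooth dome: contrast * (1 - d^2) on the elliptical support d <= 1."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dr = rr - geom["r0"]
    dc = cc - geom["c0"]
    cos_p, sin_p = math.cos(geom["phi"]), math.sin(geom["phi"])
    u = (dc * cos_p + dr * sin_p) / geom["a"]
    v = (-dc * sin_p + dr * cos_p) / geom["b"]
    d2 = u**2 + v**2
    return geom["contrast"] * np.clip(1.0 - d2, 0.0, None), d2


def generate(spec: PhantomSpec) -> tuple[Mammogram, PhantomTruth]:
    """Render one phantom and its layer-by-layer ground truth.

    The ground-truth extent of each mass is its half-maximum footprint
    (where the dome exceeds half its peak contrast), the standard
    definition of the visible extent of a smooth-edged lesion; the
    matching annotation circle has the same area as that footprint.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    center, radius = _breast_geometry(spec)
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    breast_mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2

    canvas = np.full((h, w), BACKGROUND)
    base = DENSITY_BASE[spec.density_level]
    canvas[breast_mask] = base

    pectoral_mask = np.zeros((h, w), dtype=bool)
    if spec.pectoral:
        c_extent = 0.50 * radius
        r_extent = 0.75 * radius
        col_from_chest = cc if spec.laterality == "left" else (w - 1 - cc)
        wedge = (col_from_chest / c_extent + rr / r_extent) < 1.0
        pectoral_mask = wedge & breast_mask
        canvas[pectoral_mask] += PECTORAL_CONTRAST

    gland_layer, gland_mask = _render_glands(spec, rng, breast_mask, center, radius)
    gland_layer = np.where(pectoral_mask, 0.0, gland_layer)
    gland_mask &= ~pectoral_mask

    geoms = _place_masses(spec, rng, center, radius, pectoral_mask)
    mass_layer = np.zeros((h, w))
    mass_masks: list[np.ndarray] = []
    regions: list[GroundTruthRegion] = []
    displacement = np.ones((h, w))
    for i, geom in enumerate(geoms):
        profile, d2 = _mass_profile(geom, (h, w))
        profile = ndi.gaussian_filter(profile, 1.0)
        mass_layer += profile
        displacement = np.minimum(displacement, np.clip(d2 - 0.4, 0.0, 1.0))
        footprint = (d2 <= 0.5) & breast_mask  # half-maximum extent
        mass_masks.append(footprint)
        r_eq = math.sqrt(0.5 * geom["a"] * geom["b"])
        regions.append(
            GroundTruthRegion(
                id=f"mass{i}", center=(geom["r0"], geom["c0"]), radius=r_eq
            )
        )
    # a growing mass displaces the glandular pattern around it
    gland_layer *= displacement
    gland_mask &= displacement > 0.5

    if spec.mottle_sigma > 0:
        field = ndi.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), spec.mottle_scale)
        sd = field.std()
        if sd > 0:
            canvas = canvas + breast_mask * (spec.mottle_sigma / sd) * field

    canvas = canvas + gland_layer + mass_layer
    canvas = np.where(breast_mask, canvas, BACKGROUND)

    if spec.label_artifact:
        lr0, lc0 = 12, (w - 60 if spec.laterality == "left" else 20)
        canvas[lr0 : lr0 + 20, lc0 : lc0 + 40] = 200.0

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, (h, w))
    if spec.blur_sigma > 0:
        canvas = ndi.gaussian_filter(canvas, spec.blur_sigma)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    tissue = np.zeros((h, w), dtype=np.uint8)
    tissue[breast_mask] = TISSUE_BASE
    tissue[gland_mask] = TISSUE_GLAND
    tissue[pectoral_mask] = TISSUE_PECTORAL
    for m in mass_masks:
        tissue[m] = TISSUE_MASS

    image = Mammogram(
        pixels=pixels, id=f"phantom-{spec.seed}", laterality=spec.laterality
    )
    truth = PhantomTruth(
        breast_mask=breast_mask,
        pectoral_mask=pectoral_mask,
        gland_mask=gland_mask,
        mass_masks=mass_masks,
        mass_regions=regions,
        tissue_labels=tissue,
        density_level=spec.density_level,
    )
    return image, truth


# ---------------------------------------------------------------------------
# benchmark datasets


DEFAULT_DENSITY_MIX = {"F": 0.4, "G": 0.4, "D": 0.2}


def generate_benchmark(
    n_images: int = 40,
    density_mix: dict[str, float] | None = None,
    normal_fraction: float = 0.3,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
) -> list[tuple[Mammogram, PhantomTruth]]:
    """Generate a seeded in-memory benchmark of mass and normal phantoms.

    ``normal_fraction`` of the images carry no mass (but keep glands and
    noise); the rest carry one or two.  Density levels are drawn from
    ``density_mix``.  The same seed yields an identical dataset.
    """
    mix = density_mix or DEFAULT_DENSITY_MIX
    levels = sorted(mix)
    probs = np.array([mix[l] for l in levels], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    n_normal = int(round(normal_fraction * n_images))
    dataset = []
    for i in range(n_images):
        density = str(rng.choice(levels, p=probs))
        is_normal = i < n_normal
        n_masses = 0 if is_normal else int(rng.choice([1, 2], p=[0.7, 0.3]))
        image = truth = None
        for _redraw in range(10):  # infeasible layouts are re-drawn
            child_seed = int(rng.integers(0, 2**31 - 1))
            spec = PhantomSpec(
                seed=child_seed,
                size=size,
                n_masses=n_masses,
                density_level=density,
            )
            try:
                image, truth = generate(spec)
                break
            except PlacementError:
                continue
        if image is None:
            raise PlacementError(
                f"benchmark image {i}: no feasible layout in 10 redraws"
            )
        image.id = f"phantom-{seed:04d}-{i:03d}"
        dataset.append((image, truth))
    return dataset


def make_benchmark(
    out_dir: str | Path,
    n_images: int = 40,
    density_mix: dict[str, float] | None = None,
    normal_fraction: float = 0.3,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
) -> list[tuple[Mammogram, PhantomTruth]]:
    """Write a benchmark to disk: PNG images + MIAS-dialect annotations.

    Produces ``<id>.png``, ``<id>.txt`` (one ``id col row radius`` line
    per mass, bottom-left origin; empty for normals) and a sidecar with
    laterality, consumable by the CLI end to end.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = generate_benchmark(n_images, density_mix, normal_fraction, seed, size)
    for image, truth in dataset:
        write_mammogram(image, out / f"{image.id}.png")
        write_annotations(truth.mass_regions, image, out / f"{image.id}.txt")
    return dataset
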