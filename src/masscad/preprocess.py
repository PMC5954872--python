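"""Stage-0 figure-ground segregation.

Separates the breast from the dark background and from bright label/tape
artifacts, optionally excises the pectoral-muscle wedge, and enhances
mass-like structures by morphological top-hat/bottom-hat filtering.
These are deliberately simple, well-understood operators: the detection
stages downstream are the interesting part, and each preprocessing step
can be switched off independently to study them in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, white_tophat, black_tophat
from skimage.segmentation import flood

from .errors import EmptyBreastError
from .io import Mammogram


@dataclass
class BreastMask:
    """Binary breast-region mask aligned to its Mammogram.

    ``pectoral_warning`` is set when pectoral removal hit its fail-safe
    and returned the input mask unchanged.
    """

    mask: np.ndarray
    pectoral_warning: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def segment_breast(image: Mammogram) -> BreastMask:
    """Isolate the breast as the largest bright connected component.

    A global Otsu threshold separates tissue from background; of the
    above-threshold components only the largest survives, which discards
    small bright labels and tape markings, and its holes are filled.
    """
    px = image.pixels
    if px.min() == px.max():
        raise EmptyBreastError("constant image: no foreground/background contrast")
    thresh = threshold_otsu(px)
    fg = px > thresh
    if not fg.any():
        raise EmptyBreastError("no pixel above the adaptive threshold")
    labels = label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts.argmax()
    mask = ndi.binary_fill_holes(labels == keep)
    return BreastMask(mask=mask)


def _chest_side(image: Mammogram, mask: np.ndarray) -> str:
    if image.laterality in ("left", "right"):
        return image.laterality
    # infer: the chest wall is the image edge the breast is attached to
    cols = np.flatnonzero(mask.any(axis=0))
    h_mid = mask.shape[1] / 2.0
    centroid_col = np.flatnonzero(mask.sum(axis=0)).mean() if cols.size else h_mid
    return "left" if centroid_col < h_mid else "right"


def remove_pectoral(
    image: Mammogram,
    breast: BreastMask,
    tolerance: float = 18.0,
    max_fraction: float = 0.4,
) -> BreastMask:
    """Excise the pectoral-muscle wedge from the top chest-wall corner.

    Seeded region growing starts at the top corner on the chest-wall side
    with an intensity ``tolerance``; the grown region is then clipped by a
    straight line fitted to its boundary.  If the grown area exceeds
    ``max_fraction`` of the breast the removal is aborted (the wedge is
    indistinguishable) and the input mask is returned with
    ``pectoral_warning`` set.  Never raises.
    """
    mask = breast.mask
    if breast.area == 0:
        return BreastMask(mask=mask.copy(), pectoral_warning=True)
    side = _chest_side(image, mask)
    h, w = mask.shape
    inset = 4  # keep the seed off the blurred breast boundary
    chest_col = inset if side == "left" else w - 1 - inset

    # seed: first breast pixel down the chest-wall column, pushed inward
    col_pixels = np.flatnonzero(mask[:, chest_col])
    if col_pixels.size == 0:
        return BreastMask(mask=mask.copy(), pectoral_warning=True)
    seed_row = min(int(col_pixels[0]) + inset, h - 1)
    if not mask[seed_row, chest_col]:
        seed_row = int(col_pixels[0])
    seed = (seed_row, chest_col)

    px = image.pixels.astype(np.float64)
    px_masked = np.where(mask, px, -1e6)  # growth cannot leave the breast
    grown = flood(px_masked, seed, tolerance=tolerance) & mask
    # a real pectoral wedge is a sizable structure; a sliver means there
    # was nothing to remove
    if (
        grown.sum() < 0.02 * breast.area
        or grown.sum() > max_fraction * breast.area
    ):
        return BreastMask(mask=mask.copy(), pectoral_warning=True)

    # straight-line clip: fit col = a*row + b to the grown region's inner
    # boundary (grown pixels adjacent to retained breast pixels)
    inner = grown & ndi.binary_dilation(mask & ~grown, structure=np.ones((3, 3)))
    rows, cols = np.nonzero(inner)
    new_mask = mask & ~grown
    if rows.size >= 2 and np.ptp(rows) > 0:
        a, b = np.polyfit(rows, cols, 1)
        rr, cc = np.mgrid[0:h, 0:w]
        line_col = a * rr + b
        wedge_side = cc <= line_col if side == "left" else cc >= line_col
        clipped = mask & wedge_side
        if clipped.sum() <= max_fraction * breast.area:
            new_mask = mask & ~(grown | clipped)
    if new_mask.sum() == 0:
        return BreastMask(mask=mask.copy(), pectoral_warning=True)
    return BreastMask(mask=new_mask, pectoral_warning=False)


def enhance(
    image: Mammogram,
    breast: BreastMask,
    radius: int = 30,
    fast: bool = True,
    stretch: bool = True,
) -> Mammogram:
    """Morphology-based enhancement of compact bright structures.

    output = clip(I + tophat(I, r) - bottomhat(I, r)) inside the breast;
    background is forced to exactly 0.  Structures smaller than the disk
    radius (masses, gland ridges) gain roughly their local contrast, flat
    regions are unchanged.  With ``stretch`` (the default) the result is
    then linearly mapped so the breast spans the full 8-bit range —
    standard contrast normalization, which makes downstream thresholds
    on normalized intensity independent of the film's absolute exposure.
    A constant breast region is returned unchanged (nothing to stretch).
    ``fast`` uses a sequence-decomposed disk (an octagonal approximation)
    to keep large radii affordable.
    """
    footprint = disk(radius, decomposition="sequence" if fast else None)
    px = image.pixels.astype(np.float64)
    if breast.mask.any() and not breast.mask.all():
        # fill the background with the nearest breast value so the
        # morphology does not see the breast/background step (which would
        # otherwise produce a halo of width ``radius`` along the skin line)
        _, (ir, ic) = ndi.distance_transform_edt(
            ~breast.mask, return_indices=True
        )
        px = px[ir, ic]
    th = white_tophat(px, footprint).astype(np.float64)
    bh = black_tophat(px, footprint).astype(np.float64)
    out = np.clip(px + th - bh, 0, 255)
    if stretch and breast.mask.any():
        inside = out[breast.mask]
        lo, hi = inside.min(), inside.max()
        if hi > lo:
            out = (out - lo) * (255.0 / (hi - lo))
    out = np.where(breast.mask, np.clip(out, 0, 255), 0.0)
    return Mammogram(
        pixels=np.rint(out).astype(np.uint8),
        id=image.id,
        laterality=image.laterality,
    )
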