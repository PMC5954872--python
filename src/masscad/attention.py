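"""Stage-1a visual attention: morphological saliency.

Masses read as focal bright structures.  A grayscale opening with a flat
disk (radius 6 px by default) levels narrow bright peaks while leaving
mass-scale structures intact; the regional maxima of the opened image
then mark the focal areas a reader's eye is drawn to.  Components whose
normalized peak intensity falls below the attention threshold are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label
from skimage.morphology import (
    disk,
    erosion,
    dilation,
    local_maxima,
    reconstruction,
)

from .errors import ParameterError
from .preprocess import BreastMask


@dataclass
class SaliencyMask:
    """Salient pixels (subset of the breast) and their component count."""

    mask: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def open_with_disk(
    image: np.ndarray,
    radius: int = 6,
    use_reconstruction: bool = False,
) -> np.ndarray:
    """Grayscale opening with a flat disk structuring element.

    Erosion followed by dilation with the same disk; anti-extensive
    (output <= input pointwise).  With ``use_reconstruction`` the dilation
    is replaced by morphological reconstruction of the eroded image under
    the original, which restores the exact shape of every structure that
    survives erosion.
    """
    image = np.asarray(image)
    if radius < 1:
        raise ParameterError(f"radius {radius} < 1")
    if radius > min(image.shape) / 2:
        raise ParameterError(
            f"radius {radius} exceeds half the smallest image dimension"
        )
    footprint = disk(radius)
    eroded = erosion(image, footprint)
    if use_reconstruction:
        return reconstruction(eroded, image, method="dilation").astype(image.dtype)
    return dilation(eroded, footprint)


def salient_regions(
    opened: np.ndarray,
    breast: BreastMask,
    attention_threshold: float = 0.5,
) -> SaliencyMask:
    """Regional maxima of the opened image, thresholded on peak height.

    A regional maximum is a connected plateau (8-connectivity) with no
    strictly brighter neighbor.  Maxima are intersected with the breast;
    components whose peak intensity, normalized by 255, falls below
    ``attention_threshold`` are dropped.  May return an empty mask.
    """
    opened = np.asarray(opened)
    if opened.shape != breast.mask.shape:
        raise ParameterError("opened image and breast mask are not aligned")
    maxima = local_maxima(opened, connectivity=2) & breast.mask
    labels, n = label(maxima, connectivity=2, return_num=True)
    if n == 0:
        return SaliencyMask(mask=np.zeros_like(maxima), n_components=0)
    peaks = ndi.maximum(opened, labels, index=np.arange(1, n + 1))
    good = np.flatnonzero(np.asarray(peaks) / 255.0 >= attention_threshold) + 1
    keep = np.isin(labels, good)
    return SaliencyMask(mask=keep, n_components=int(good.size))
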