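"""Image, annotation and detection I/O plus the shared domain types.

Coordinate convention: row-major, 0-based, origin at the top-left corner,
``(row, col)`` order everywhere in the package.  MIAS-style annotation
files store ``id center_col center_row radius`` with, in some
distributions, a bottom-left origin; :func:`read_annotations` applies the
vertical flip when ``origin="bottom-left"`` (the default, matching the
files this package writes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import AnnotationError, FormatError
from .config import PipelineConfig

LATERALITIES = ("left", "right", "unknown")


@dataclass
class Mammogram:
    """A single-view digitized mammogram.

    ``pixels`` is a 2-D uint8 array of gray intensity in [0, 255];
    images are at least 64 px on a side.
    """

    pixels: np.ndarray
    id: str = ""
    laterality: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"expected 2-D pixel array, got {px.ndim}-D")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise FormatError(f"image {px.shape} smaller than 64x64")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(np.isfinite(px)):
                raise FormatError("non-finite pixel values")
        if px.min() < 0 or px.max() > 255:
            raise FormatError("intensities outside the 8-bit range [0, 255]")
        if self.laterality not in LATERALITIES:
            raise FormatError(f"laterality {self.laterality!r} not in {LATERALITIES}")
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GroundTruthRegion:
    """An expert mass annotation: either a circle or a binary mask.

    Exactly one of (``center``, ``radius``) or ``mask`` is present.
    ``center`` is in (row, col) order.
    """

    id: str = ""
    center: tuple[float, float] | None = None
    radius: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        has_circle = self.center is not None or self.radius is not None
        has_mask = self.mask is not None
        if has_circle == has_mask:
            raise AnnotationError(
                f"region {self.id!r}: exactly one of circle or mask required"
            )
        if has_circle:
            if self.center is None or self.radius is None:
                raise AnnotationError(f"region {self.id!r}: incomplete circle")
            if self.radius <= 0:
                raise AnnotationError(f"region {self.id!r}: radius {self.radius} <= 0")
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.sum() < 1:
                raise AnnotationError(f"region {self.id!r}: empty mask")

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise AnnotationError(
                    f"region {self.id!r}: mask shape {self.mask.shape} != {shape}"
                )
            return
        r, c = self.center
        if (
            r - self.radius < 0
            or c - self.radius < 0
            or r + self.radius > shape[0] - 1
            or c + self.radius > shape[1] - 1
        ):
            raise AnnotationError(
                f"region {self.id!r}: circle ({r}, {c}) radius {self.radius} "
                f"exceeds image bounds {shape}"
            )

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean mask aligned to an image of ``shape``."""
        if self.mask is not None:
            return self.mask
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        r0, c0 = self.center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2


# ---------------------------------------------------------------------------
# images


def read_mammogram(path: str | Path, laterality: str | None = None) -> Mammogram:
    """Read an 8- or 16-bit single-channel raster (PGM/PNG/TIFF).

    16-bit inputs are rescaled to [0, 255] by a linear min-max mapping.
    Laterality comes from an optional ``<stem>.json`` sidecar
    (``{"laterality": "left"}``) when not given explicitly.
    """
    p = Path(path)
    try:
        img = Image.open(p)
        img.load()
    except Exception as exc:  # noqa: BLE001 - PIL raises many types
        raise OSError(f"cannot read image {p}: {exc}") from exc
    bands = img.getbands()
    if len(bands) != 1:
        raise FormatError(f"{p}: expected single-channel image, got {len(bands)} channels")
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) * (255.0 / (hi - lo))
        else:
            arr = np.zeros_like(arr)
        arr = np.rint(arr).astype(np.uint8)
    if laterality is None:
        laterality = "unknown"
        sidecar = p.with_suffix(".json")
        if sidecar.exists():
            try:
                meta = json.loads(sidecar.read_text())
                laterality = meta.get("laterality", "unknown")
            except (json.JSONDecodeError, OSError):
                laterality = "unknown"
    return Mammogram(pixels=arr, id=p.stem, laterality=laterality)


def write_mammogram(image: Mammogram, path: str | Path) -> None:
    p = Path(path)
    Image.fromarray(image.pixels).save(p)
    if image.laterality != "unknown":
        p.with_suffix(".json").write_text(
            json.dumps({"laterality": image.laterality})
        )


# ---------------------------------------------------------------------------
# annotations


def read_annotations(
    path: str | Path,
    image: Mammogram,
    origin: str = "bottom-left",
) -> list[GroundTruthRegion]:
    """Read mass annotations for ``image``.

    A text file holds one region per line, ``id center_col center_row
    radius``; an image file path is treated as a single binary mask.
    ``origin`` selects the vertical coordinate convention of the file
    ("bottom-left" rows count up from the bottom edge, MIAS style).
    """
    p = Path(path)
    if p.suffix.lower() in (".png", ".pgm", ".tif", ".tiff"):
        mask = np.asarray(Image.open(p)) > 0
        region = GroundTruthRegion(id=p.stem, mask=mask)
        region.validate_bounds(image.shape)
        return [region]
    if origin not in ("top-left", "bottom-left"):
        raise AnnotationError(f"unknown origin convention {origin!r}")
    regions: list[GroundTruthRegion] = []
    for lineno, line in enumerate(p.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise AnnotationError(f"{p}:{lineno}: expected 4 fields, got {len(parts)}")
        rid, col_s, row_s, rad_s = parts
        try:
            col, row, rad = float(col_s), float(row_s), float(rad_s)
        except ValueError as exc:
            raise AnnotationError(f"{p}:{lineno}: non-numeric field") from exc
        if origin == "bottom-left":
            row = image.height - 1 - row
        region = GroundTruthRegion(id=rid, center=(row, col), radius=rad)
        region.validate_bounds(image.shape)
        regions.append(region)
    return regions


def write_annotations(
    regions: list[GroundTruthRegion],
    image: Mammogram,
    path: str | Path,
    origin: str = "bottom-left",
) -> None:
    lines = []
    for reg in regions:
        if reg.center is None:
            raise AnnotationError(
                f"region {reg.id!r}: only circle regions serialize to text"
            )
        row, col = reg.center
        if origin == "bottom-left":
            row = image.height - 1 - row
        lines.append(f"{reg.id} {col:g} {row:g} {reg.radius:g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# run-length encoding and detection documents


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major starts/lengths)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "starts": [], "lengths": []}
    diff = np.diff(flat.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if flat[0]:
        starts = np.r_[0, starts]
    if flat[-1]:
        ends = np.r_[ends, flat.size]
    return {
        "shape": list(mask.shape),
        "starts": starts.tolist(),
        "lengths": (ends - starts).tolist(),
    }


def rle_decode(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for s, l in zip(rle["starts"], rle["lengths"]):
        flat[s : s + l] = True
    return flat.reshape(shape)


def save_detections(result, path: str | Path) -> None:
    """Serialize a DetectionResult to one JSON document per image."""
    doc = {
        "image_id": result.image_id,
        "shape": list(result.shape),
        "config": result.config.to_dict() if result.config else None,
        "rois": [
            {
                "patch_ids": sorted(int(i) for i in roi.patch_ids),
                "score": float(roi.score),
                "label": roi.label,
                "features": [float(v) for v in roi.features],
                "mask": rle_encode(roi.mask),
            }
            for roi in result.rois
        ],
        "provenance": result.provenance.to_dict() if result.provenance else None,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_detections(path: str | Path):
    """Load a detection JSON document written by :func:`save_detections`."""
    from .verification import ROI
    from .pipeline import DetectionResult, StageProvenance

    doc = json.loads(Path(path).read_text())
    rois = [
        ROI(
            patch_ids=frozenset(r["patch_ids"]),
            mask=rle_decode(r["mask"]),
            features=np.asarray(r["features"], dtype=float),
            score=r["score"],
            label=r["label"],
        )
        for r in doc["rois"]
    ]
    prov = (
        StageProvenance.from_dict(doc["provenance"]) if doc.get("provenance") else None
    )
    cfg = PipelineConfig.from_dict(doc["config"]) if doc.get("config") else None
    return DetectionResult(
        image_id=doc["image_id"],
        shape=tuple(doc["shape"]),
        rois=rois,
        provenance=prov,
        config=cfg,
    )
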