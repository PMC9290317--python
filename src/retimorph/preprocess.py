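"""Fundus preprocessing: retinal-field masking and square cropping.

Color fundus photographs usually carry a large dark border around the
circular retinal field.  This module estimates a binary mask of the
retinal field (grayscale conversion, global threshold, morphological
opening/closing, largest connected component, hole filling) and crops
the photograph to a tight geometric square around it, recording the
transform so output coordinates can be mapped back to the original
frame exactly.

Coordinate convention used throughout the package: row-major, 0-based,
top-left origin, half-open bounding boxes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color, filters, measure, morphology


class FundusMaskError(ValueError):
    """Raised when no retinal field can be found in an image."""


@dataclass(frozen=True)
class CropRecord:
    """Provenance of a square crop.

    ``row_offset``/``col_offset`` are the coordinates, in the original
    frame, of the output's top-left pixel.  Under the ``pad`` policy the
    square may extend past the original frame, in which case offsets are
    negative; under ``clip`` they satisfy ``0 <= offset`` and
    ``offset + side <= original dimension``.
    """

    row_offset: int
    col_offset: int
    side: int
    mask_area_fraction: float
    clipped_warning: bool = False

    def to_input_coords(self, row: float, col: float) -> tuple[float, float]:
        """Map output (cropped) coordinates back to the original frame."""
        return row + self.row_offset, col + self.col_offset


@dataclass
class FundusImage:
    """An RGB fundus photograph with optional crop provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8
    source_id: str = ""
    crop: Optional[CropRecord] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB raster")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _structuring_disk(shape: tuple[int, int]) -> np.ndarray:
    # scale-free: radius grows with image size but never below 3 px
    radius = max(3, int(round(0.01 * min(shape))))
    return morphology.disk(radius)


def estimate_fundus_mask(
    image: FundusImage,
    intensity_threshold: int = 10,
    otsu_fallback: bool = True,
    min_area_fraction: float = 0.05,
) -> np.ndarray:
    """Estimate the binary mask of the retinal field.

    Grayscale conversion uses standard luma weighting.  A fixed global
    threshold separates the bright fundus from the dark background; if
    the result covers less than ``min_area_fraction`` of the frame and
    ``otsu_fallback`` is set, Otsu's threshold is tried instead.  The
    thresholded mask is cleaned with a morphological opening then
    closing (disk element scaled to the frame), reduced to its largest
    connected component, and hole-filled.

    Raises
    ------
    FundusMaskError
        If no foreground pixel survives ("no fundus region found").
    """
    if not 0 <= intensity_threshold <= 255:
        raise ValueError("intensity_threshold must be in [0, 255]")
    gray = color.rgb2gray(image.pixels)  # float in [0, 1]
    raw = gray > intensity_threshold / 255.0
    if otsu_fallback and raw.mean() < min_area_fraction and gray.max() > gray.min():
        raw = gray > filters.threshold_otsu(gray)
    if not raw.any():
        raise FundusMaskError("no fundus region found")

    selem = _structuring_disk(image.shape)
    mask = morphology.opening(raw, selem)
    mask = morphology.closing(mask, selem)
    if not mask.any():
        raise FundusMaskError("no fundus region found")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    mask = ndimage.binary_fill_holes(mask)
    return mask


def crop_to_square(
    image: FundusImage,
    mask: np.ndarray,
    pad_policy: str = "pad",
) -> FundusImage:
    """Crop an image to a square around the mask's bounding box.

    The square side equals the larger dimension of the mask's bounding
    box and is centered on it.  ``pad_policy="pad"`` extends with black
    when the square exceeds the frame (the mask is then always fully
    contained); ``"clip"`` shifts/truncates the square to stay inside
    the frame.  If the mask touches all four borders under ``clip``,
    the center square of the full frame is returned with a warning
    flag in the :class:`CropRecord`.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask geometry does not match image")
    if not mask.any():
        raise FundusMaskError("empty mask")
    if pad_policy not in ("pad", "clip"):
        raise ValueError(f"unknown pad_policy {pad_policy!r}")

    h, w = image.shape
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1  # half-open
    c0, c1 = cols[0], cols[-1] + 1
    side = max(r1 - r0, c1 - c0)

    # center the square on the bounding box
    row_off = r0 - (side - (r1 - r0)) // 2
    col_off = c0 - (side - (c1 - c0)) // 2
    warning = False

    if pad_policy == "clip":
        touches_all = r0 == 0 and c0 == 0 and r1 == h and c1 == w
        if touches_all and side > min(h, w):
            side = min(h, w)
            row_off = (h - side) // 2
            col_off = (w - side) // 2
            warning = True
        else:
            side = min(side, h, w)
            row_off = int(np.clip(row_off, 0, h - side))
            col_off = int(np.clip(col_off, 0, w - side))

    out = np.zeros((side, side, 3), dtype=np.uint8)
    src_r0, src_r1 = max(row_off, 0), min(row_off + side, h)
    src_c0, src_c1 = max(col_off, 0), min(col_off + side, w)
    dst_r0, dst_c0 = src_r0 - row_off, src_c0 - col_off
    out[dst_r0 : dst_r0 + (src_r1 - src_r0), dst_c0 : dst_c0 + (src_c1 - src_c0)] = (
        image.pixels[src_r0:src_r1, src_c0:src_c1]
    )

    record = CropRecord(
        row_offset=int(row_off),
        col_offset=int(col_off),
        side=int(side),
        mask_area_fraction=float(mask.mean()),
        clipped_warning=warning,
    )
    return FundusImage(pixels=out, source_id=image.source_id, crop=record)


def preprocess_image(
    image: FundusImage,
    intensity_threshold: int = 10,
    pad_policy: str = "pad",
) -> FundusImage:
    """Mask the retinal field and crop to a square in one step."""
    mask = estimate_fundus_mask(image, intensity_threshold=intensity_threshold)
    return crop_to_square(image, mask, pad_policy=pad_policy)


def load_image(path: str | Path, source_id: str | None = None) -> FundusImage:
    """Read a PNG/JPEG photograph as a :class:`FundusImage`."""
    path = Path(path)
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    return FundusImage(pixels=px, source_id=source_id or path.stem)


def save_image(image: FundusImage, path: str | Path) -> None:
    Image.fromarray(image.pixels).save(Path(path))


def write_crop_records(records: Iterable[tuple[str, CropRecord]], path: str | Path) -> None:
    """Write a sidecar CSV of crop provenance (one row per image)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "row_offset", "col_offset", "side"])
        for source_id, rec in records:
            writer.writerow([source_id, rec.row_offset, rec.col_offset, rec.side])
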