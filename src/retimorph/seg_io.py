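"""Segmentation-map thresholding and mask I/O.

Probability maps from the (pluggable) segmentation models are converted
to discrete anatomy masks: the binary vessel map is thresholded at 0.5
(ties count as vessel), artery/vein maps take the per-pixel argmax over
the four classes (artery, vein, uncertain, background; ties broken in
that order), and the optic-disc mask is reduced to a scalar geometry
(centroid, bounding-box extents, diameter) for zone construction.

Masks are stored as 8-bit PNG: binary masks as 255/0, artery/vein maps
in a palette (artery=red, vein=blue, uncertain=green, background=black).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage

# artery/vein label raster values
AV_BACKGROUND = 0
AV_ARTERY = 1
AV_VEIN = 2
AV_UNCERTAIN = 3

_AV_PALETTE = {
    AV_BACKGROUND: (0, 0, 0),
    AV_ARTERY: (255, 0, 0),
    AV_VEIN: (0, 0, 255),
    AV_UNCERTAIN: (0, 255, 0),
}


@dataclass(frozen=True)
class DiscGeometry:
    """Scalar geometry of the optic disc: centroid, extents, diameter."""

    center: tuple[float, float]  # (row, col)
    height: int
    width: int

    @property
    def diameter(self) -> float:
        # the disc is roughly elliptical; a symmetric scalar diameter is
        # the mean of the bounding-box extents
        return (self.height + self.width) / 2.0


@dataclass
class SegmentationBundle:
    """All segmentation outputs for one image, on a shared raster.

    The artery/vein raster comes from an independent model, so its
    vessel pixels need not coincide with ``vessel_mask``.
    """

    vessel_mask: np.ndarray
    av_labels: Optional[np.ndarray] = None
    disc_mask: Optional[np.ndarray] = None
    cup_mask: Optional[np.ndarray] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        geom = self.vessel_mask.shape
        for name in ("av_labels", "disc_mask", "cup_mask"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr)
            if arr.shape != geom:
                raise ValueError(f"{name} geometry {arr.shape} != {geom}")
            setattr(self, name, arr.astype(bool) if name != "av_labels" else arr.astype(np.uint8))

    @property
    def geometry(self) -> tuple[int, int]:
        return self.vessel_mask.shape


def binarize_vessel(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a vessel probability map; pixel is vessel iff p >= threshold."""
    p = np.asarray(prob_map, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probability map values must lie in [0, 1]")
    return p >= threshold


def resolve_av(prob_maps: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over 4 channels (artery, vein, uncertain, background).

    Ties are broken deterministically by the fixed channel order
    artery > vein > uncertain > background.  Returns a uint8 label
    raster with the ``AV_*`` values.
    """
    p = np.asarray(prob_maps, dtype=float)
    if p.ndim != 3 or p.shape[2] != 4:
        raise ValueError("expected an (H, W, 4) probability raster")
    # channels ordered artery, vein, uncertain, background; argmax picks
    # the first maximum, matching the tie-break order
    arg = np.argmax(p, axis=2)
    labels = np.empty(arg.shape, dtype=np.uint8)
    mapping = (AV_ARTERY, AV_VEIN, AV_UNCERTAIN, AV_BACKGROUND)
    for ch, lab in enumerate(mapping):
        labels[arg == ch] = lab
    return labels


def disc_geometry(disc_mask: np.ndarray) -> DiscGeometry:
    """Measure centroid, bounding-box extents, and diameter of the disc.

    The largest connected component is kept; the diameter is the mean
    of the bounding-box height and width.
    """
    mask = np.asarray(disc_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no disc")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r, c = np.nonzero(mask)
    return DiscGeometry(
        center=(float(r.mean()), float(c.mean())),
        height=int(rows[-1] - rows[0] + 1),
        width=int(cols[-1] - cols[0] + 1),
    )


# ---------------------------------------------------------------------------
# PNG / numeric raster I/O


def save_binary_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(Path(path))


def load_binary_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return arr >= 128


def save_av_labels(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    rgb = np.zeros((*labels.shape, 3), dtype=np.uint8)
    for value, color in _AV_PALETTE.items():
        rgb[labels == value] = color
    Image.fromarray(rgb).save(Path(path))


def load_av_labels(path: str | Path) -> np.ndarray:
    rgb = np.asarray(Image.open(Path(path)).convert("RGB"))
    labels = np.full(rgb.shape[:2], AV_BACKGROUND, dtype=np.uint8)
    for value, color in _AV_PALETTE.items():
        if value == AV_BACKGROUND:
            continue
        labels[np.all(rgb == color, axis=2)] = value
    return labels


def load_probability_map(path: str | Path) -> np.ndarray:
    """Read a probability raster: .npy/.npz numeric, or 8-bit PNG scaled to [0, 1]."""
    path = Path(path)
    if path.suffix in (".npy", ".npz"):
        arr = np.load(path)
        if isinstance(arr, np.lib.npyio.NpzFile):
            arr = arr[arr.files[0]]
        return np.asarray(arr, dtype=float)
    img = np.asarray(Image.open(path))
    return img.astype(float) / 255.0


def write_bundle(bundle: SegmentationBundle, out_dir: str | Path, stem: str | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or bundle.source_id or "image"
    save_binary_mask(bundle.vessel_mask, out / f"{stem}_vessel.png")
    if bundle.av_labels is not None:
        save_av_labels(bundle.av_labels, out / f"{stem}_av.png")
    if bundle.disc_mask is not None:
        save_binary_mask(bundle.disc_mask, out / f"{stem}_disc.png")
    if bundle.cup_mask is not None:
        save_binary_mask(bundle.cup_mask, out / f"{stem}_cup.png")


def read_bundle(in_dir: str | Path, stem: str) -> SegmentationBundle:
    """Read a mask bundle written by :func:`write_bundle`; optional parts may be absent."""
    in_dir = Path(in_dir)
    vessel_path = in_dir / f"{stem}_vessel.png"
    if not vessel_path.exists():
        raise FileNotFoundError(vessel_path)
    vessel = load_binary_mask(vessel_path)

    def _opt(loader, name):
        p = in_dir / f"{stem}_{name}.png"
        return loader(p) if p.exists() else None

    return SegmentationBundle(
        vessel_mask=vessel,
        av_labels=_opt(load_av_labels, "av"),
        disc_mask=_opt(load_binary_mask, "disc"),
        cup_mask=_opt(load_binary_mask, "cup"),
        source_id=stem,
    )
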