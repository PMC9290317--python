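"""Vessel skeletonization, segment decomposition, and caliber estimation.

A binary vessel mask is thinned to a one-pixel-wide, 8-connected,
topology-preserving skeleton.  The skeleton is split at branch points
(pixels with three or more skeleton neighbours) into maximal
branch-free *segments*: ordered centerline paths with per-point
calibers.  Caliber at a centerline point is twice the Euclidean
distance-transform value of the mask there — the diameter of the
largest disk centered on the point that fits inside the vessel.

Short terminal twigs produced by thinning ("spurs") are pruned
iteratively before measurement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

_SQRT2 = float(np.sqrt(2.0))
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])

#: spur-pruning default: twigs shorter than this (or 2x the local
#: caliber, whichever is larger) are removed
DEFAULT_SPUR_LENGTH = 10.0


@dataclass
class VesselSegment:
    """An ordered branch-free centerline path with per-point calibers."""

    points: np.ndarray  # (N, 2) int row/col, consecutive points 8-adjacent
    widths: Optional[np.ndarray] = None  # (N,) caliber in pixels
    label: str = "unknown"  # artery / vein / unknown
    segment_id: int = -1
    closed: bool = False  # ring: endpoints coincide, chord undefined

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("segment needs >= 2 (row, col) points")
        steps = np.abs(np.diff(pts, axis=0))
        if steps.max() > 1:
            raise ValueError("consecutive centerline points must be 8-neighbors")
        self.points = pts
        if self.widths is not None:
            self.widths = np.asarray(self.widths, dtype=float)
            if self.widths.shape != (len(pts),):
                raise ValueError("widths must align with points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def arc_length(self) -> float:
        """Polyline length: 1 per axial step, sqrt(2) per diagonal step."""
        steps = np.abs(np.diff(self.points, axis=0))
        diagonal = steps.all(axis=1)
        return float(np.where(diagonal, _SQRT2, 1.0).sum())

    @property
    def chord_length(self) -> float:
        """Euclidean distance between the endpoints (0 for a closed ring)."""
        if self.closed:
            return 0.0
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def mean_width(self) -> float:
        if self.widths is None:
            raise ValueError("widths not estimated")
        return float(self.widths.mean())


@dataclass
class SkeletonGraph:
    """A skeleton mask decomposed into branch-free segments."""

    skeleton_mask: np.ndarray
    segments: List[VesselSegment] = field(default_factory=list)

    @property
    def junctions(self) -> np.ndarray:
        return _junction_mask(self.skeleton_mask)

    @property
    def endpoints(self) -> np.ndarray:
        nb = _neighbor_count(self.skeleton_mask)
        return self.skeleton_mask & (nb == 1)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide, 8-connected, topology-preserving medial skeleton."""
    return morphology.skeletonize(np.asarray(mask, dtype=bool))


def _neighbor_count(skeleton: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skeleton.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def _junction_mask(skeleton: np.ndarray) -> np.ndarray:
    return skeleton & (_neighbor_count(skeleton) >= 3)


def _trace_component(coords: np.ndarray) -> tuple[np.ndarray, bool]:
    """Order the pixels of one branch-free component into a path.

    Returns (ordered points, closed flag).  A component without a
    degree-1 pixel is a closed ring; its path is closed by repeating
    the first point at the end.
    """
    coord_set = {tuple(p) for p in coords}
    neighbors = {}
    for p in coord_set:
        nbs = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (p[0] + dr, p[1] + dc)
                if q in coord_set:
                    nbs.append(q)
        neighbors[p] = nbs
    ends = sorted(p for p, nbs in neighbors.items() if len(nbs) <= 1)
    start = ends[0] if ends else min(coord_set)
    closed = not ends

    path = [start]
    visited = {start}
    current = start
    while True:
        nxt = [q for q in neighbors[current] if q not in visited]
        if not nxt:
            break
        # prefer axial moves so stair-step pixels stay in order
        nxt.sort(key=lambda q: (abs(q[0] - current[0]) + abs(q[1] - current[1]), q))
        current = nxt[0]
        path.append(current)
        visited.add(current)
    if closed and len(path) > 2:
        path.append(start)
    return np.array(path, dtype=int), closed


def decompose_segments(skeleton: np.ndarray) -> List[VesselSegment]:
    """Split a 1-px skeleton into maximal branch-free segments.

    Branch (junction) pixels — those with >= 3 skeleton neighbours —
    belong to no segment, so non-junction pixels appear in exactly one
    segment.  Each segment is ordered from one endpoint to the other;
    an isolated ring becomes one segment with coincident endpoints.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    paths = skeleton & ~_junction_mask(skeleton)
    labels, n = ndimage.label(paths, structure=np.ones((3, 3)))
    segments: List[VesselSegment] = []
    sid = 0
    for comp in range(1, n + 1):
        coords = np.argwhere(labels == comp)
        if len(coords) < 2:
            continue  # isolated pixel between junctions carries no geometry
        pts, closed = _trace_component(coords)
        segments.append(VesselSegment(points=pts, segment_id=sid, closed=closed))
        sid += 1
    return segments


def estimate_widths(mask: np.ndarray, segment: VesselSegment) -> np.ndarray:
    """Per-point caliber: 2 x Euclidean distance transform of the mask.

    Raises if a centerline point falls outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = segment.points[:, 0], segment.points[:, 1]
    if not mask[rows, cols].all():
        raise ValueError("centerline point outside vessel mask")
    dt = ndimage.distance_transform_edt(mask)
    widths = 2.0 * dt[rows, cols]
    segment.widths = widths
    return widths


def prune_spurs(
    graph: SkeletonGraph,
    min_length: float = DEFAULT_SPUR_LENGTH,
    mask: Optional[np.ndarray] = None,
) -> SkeletonGraph:
    """Remove short terminal segments, repeating until a fixed point.

    A terminal segment has at least one free end (an endpoint touching
    no junction).  It is pruned when its arc length falls below
    ``min_length`` or, when ``mask`` is given, below twice the local
    caliber at its attached end — thinning hairs scale with vessel
    width, capillaries do not.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    skeleton = graph.skeleton_mask.copy()
    dt = ndimage.distance_transform_edt(mask) if mask is not None else None
    while True:
        junctions = _junction_mask(skeleton)
        segments = decompose_segments(skeleton)
        removed = False
        for seg in segments:
            if seg.closed:
                continue
            free_ends = []
            for end in (seg.points[0], seg.points[-1]):
                r0, r1 = max(end[0] - 1, 0), end[0] + 2
                c0, c1 = max(end[1] - 1, 0), end[1] + 2
                free_ends.append(not junctions[r0:r1, c0:c1].any())
            if not any(free_ends):
                continue  # internal segment between two junctions
            threshold = min_length
            if dt is not None:
                attach = seg.points[-1] if free_ends[0] else seg.points[0]
                threshold = max(threshold, 4.0 * float(dt[attach[0], attach[1]]))
            if seg.arc_length < threshold and not all(free_ends):
                # keep isolated segments (both ends free): they are whole
                # vessels, not thinning artifacts
                skeleton[seg.points[:, 0], seg.points[:, 1]] = False
                removed = True
        if not removed:
            break
        # re-thin: junction clusters can leave bump pixels behind once
        # their spur is gone, which would otherwise split the main path
        skeleton = morphology.skeletonize(skeleton)
    return SkeletonGraph(skeleton_mask=skeleton, segments=decompose_segments(skeleton))


def build_graph(
    mask: np.ndarray,
    spur_min_length: float = DEFAULT_SPUR_LENGTH,
    estimate_caliber: bool = True,
) -> SkeletonGraph:
    """Skeletonize a vessel mask, prune spurs, and measure calibers."""
    mask = np.asarray(mask, dtype=bool)
    skeleton = skeletonize(mask)
    graph = SkeletonGraph(skeleton_mask=skeleton, segments=decompose_segments(skeleton))
    if spur_min_length > 0:
        graph = prune_spurs(graph, min_length=spur_min_length, mask=mask)
    if estimate_caliber and mask.any():
        dt = ndimage.distance_transform_edt(mask)
        for seg in graph.segments:
            seg.widths = 2.0 * dt[seg.points[:, 0], seg.points[:, 1]]
    return graph


def write_segment_table(segments: Sequence[VesselSegment], path: str | Path) -> None:
    """Segment summary CSV: id, label, n_points, arc, chord, mean width."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["segment_id", "label", "n_points", "arc_length", "chord_length", "mean_width"]
        )
        for seg in segments:
            mean_w = f"{seg.mean_width:.4f}" if seg.widths is not None else ""
            writer.writerow(
                [
                    seg.segment_id,
                    seg.label,
                    seg.n_points,
                    f"{seg.arc_length:.4f}",
                    f"{seg.chord_length:.4f}",
                    mean_w,
                ]
            )
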