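"""Shared fixtures: rasterized curves and synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest
from skimage import draw

from retimorph.vessel_graph import VesselSegment, decompose_segments


def chain_from_polyline(polyline: np.ndarray) -> np.ndarray:
    """Rasterize a float polyline into an 8-connected pixel chain."""
    rowcol = np.round(polyline).astype(int)
    pts = [tuple(rowcol[0])]
    for rc in map(tuple, rowcol):
        if rc == pts[-1]:
            continue
        pr, pc = pts[-1]
        while max(abs(rc[0] - pr), abs(rc[1] - pc)) > 1:
            pr += int(np.sign(rc[0] - pr))
            pc += int(np.sign(rc[1] - pc))
            pts.append((pr, pc))
        if rc != pts[-1]:
            pts.append(rc)
    return np.array(pts, dtype=int)


def semicircle_chain(radius: int, center=(300, 300), frame=(600, 600)) -> np.ndarray:
    """Upper-half circle as an ordered 8-connected pixel chain."""
    rr, cc = draw.circle_perimeter(center[0], center[1], radius, method="bresenham")
    mask = np.zeros(frame, dtype=bool)
    keep = rr <= center[0]
    mask[rr[keep], cc[keep]] = True
    segments = decompose_segments(mask)
    return max(segments, key=lambda s: s.n_points).points


def sine_chain(amplitude: float, x_scale: float, t0: float, t1: float, n: int = 6000) -> np.ndarray:
    """Rasterized sine curve row = A sin(t), col = x_scale * (t - t0)."""
    t = np.linspace(t0, t1, n)
    poly = np.column_stack([300 + amplitude * np.sin(t), 50 + x_scale * (t - t0)])
    return chain_from_polyline(poly)


@pytest.fixture
def straight_segment() -> VesselSegment:
    pts = np.column_stack([np.full(100, 50), np.arange(100)])
    return VesselSegment(points=pts)


@pytest.fixture
def semicircle_segment() -> VesselSegment:
    return VesselSegment(points=semicircle_chain(50))


@pytest.fixture(scope="session")
def default_scene():
    """One rendered synthetic scene with its truth ledger (seed 3)."""
    from retimorph.synthetic import TreeSpec, generate_vessel_scene

    return generate_vessel_scene(TreeSpec(seed=3))
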