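"""Synthetic fundus scenes with exact ground truth.

The generator renders a stylized retinal scene — an elliptical optic
disc and cup, and vessel trees radiating outward from the disc margin
with prescribed widths, sinusoidal waviness, and alternating
artery/vein labels — together with a *truth ledger* recording every
centerline polyline, drawn width, label, and analytic arc/chord
length.  Morphometry can then be validated against known answers
without any real photographs or trained models.

Emulated: bright circular fundus field on dark background, tubular
vessels of controlled caliber and tortuosity, disc/cup ellipses,
ensemble probability draws with controllable spread.  Not emulated:
texture, pathology, illumination gradients, vessel crossings and
caliber taper — so a passing ledger-closure test demonstrates metric
correctness, not robustness to real-image segmentation noise.

All randomness flows from the single seed in :class:`TreeSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from skimage import draw

from .quality import CLASS_NAMES, EnsembleGrades
from .seg_io import AV_ARTERY, AV_VEIN, SegmentationBundle, write_bundle


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of one synthetic vessel scene.

    Defaults draw 14 roots (7 arteries, 7 veins alternating) from a
    diameter-100 disc centered in a 768x768 frame, widths stepping down
    from 15 px by 2 within each label so caliber ranking is unambiguous,
    with gentle waviness (2 px amplitude over a 60 px period).  The
    frame comfortably contains measurement Zone C (outer radius 250 px).
    """

    seed: int = 0
    frame: tuple[int, int] = (768, 768)
    disc_center: Optional[tuple[float, float]] = None  # default: frame center
    disc_diameter: float = 100.0
    cup_ratio: float = 0.5  # cup extent / disc extent
    n_roots: int = 14
    width_root: float = 15.0
    width_min: float = 3.0
    width_decay: float = 0.85  # per-branch caliber ratio
    branch_prob: float = 0.0  # per-step probability of spawning a branch
    waviness_amplitude: float = 2.0  # px
    waviness_period: float = 60.0  # px along the vessel
    vessel_reach: float = 2.2  # outer extent, in disc diameters past the margin
    angle_jitter: float = 0.05  # radians, per root


@dataclass
class TruthSegment:
    """Ground truth for one drawn vessel."""

    root_id: int
    label: str  # artery / vein
    polyline: np.ndarray  # (N, 2) float row/col samples, 1 px apart
    width: float  # drawn caliber in px

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.polyline[-1] - self.polyline[0]))

    @property
    def distance_tortuosity(self) -> float:
        return self.arc_length / self.chord_length


@dataclass
class TruthLedger:
    """Everything the generator knows about a rendered scene."""

    segments: List[TruthSegment] = field(default_factory=list)
    vessel_area: int = 0
    disc_extent: tuple[int, int] = (0, 0)  # (height, width)
    cup_extent: tuple[int, int] = (0, 0)
    frame: tuple[int, int] = (0, 0)

    def widths_by_label(self, label: str) -> List[float]:
        """Drawn widths of one label, sorted descending."""
        return sorted(
            (s.width for s in self.segments if s.label == label), reverse=True
        )


def _root_width(spec: TreeSpec, root_index: int) -> float:
    # widths step down by 2 px within each label: 15, 13, 11, ... for
    # arteries (even indices) and likewise for veins — distinct values
    # make six-widest selection checkable against the ledger
    return max(spec.width_min, spec.width_root - 2.0 * (root_index // 2))


def _stamp_tube(canvas: np.ndarray, polyline: np.ndarray, width: float) -> None:
    """Mark all pixels within (width - 1) / 2 of the polyline samples."""
    radius = max((width - 1.0) / 2.0, 0.0)
    h, w = canvas.shape
    for point in polyline:
        rr, cc = draw.disk((point[0], point[1]), radius + 0.5, shape=(h, w))
        canvas[rr, cc] = True


def generate_vessel_scene(spec: TreeSpec) -> tuple[SegmentationBundle, TruthLedger]:
    """Render one synthetic scene; deterministic per seed.

    Roots are evenly spaced in angle (with seeded jitter), start at the
    disc margin, and run radially outward with a sinusoidal lateral
    offset.  Widths are constant along a root; branches (when
    ``branch_prob`` > 0) inherit ``width_decay`` times the parent
    caliber.  The returned ledger's polylines are the exact continuous
    centerlines the tubes were stamped from.
    """
    h, w = spec.frame
    center = spec.disc_center or ((h - 1) / 2.0, (w - 1) / 2.0)
    disc_r = spec.disc_diameter / 2.0
    reach = disc_r + spec.vessel_reach * spec.disc_diameter
    if reach + spec.width_root >= min(center[0], center[1], h - 1 - center[0], w - 1 - center[1]):
        raise ValueError("frame too small for the requested vessel reach")

    rng = np.random.default_rng(spec.seed)
    vessel = np.zeros((h, w), dtype=bool)
    av = np.zeros((h, w), dtype=np.uint8)
    ledger = TruthLedger(frame=(h, w))

    base_angles = np.linspace(0, 2 * np.pi, spec.n_roots, endpoint=False)
    jitter = rng.uniform(-spec.angle_jitter, spec.angle_jitter, spec.n_roots)
    phases = rng.uniform(0, 2 * np.pi, spec.n_roots)

    for i in range(spec.n_roots):
        theta = base_angles[i] + jitter[i]
        label = "artery" if i % 2 == 0 else "vein"
        width = _root_width(spec, i)
        u = np.array([np.sin(theta), np.cos(theta)])  # radial direction (row, col)
        v = np.array([np.cos(theta), -np.sin(theta)])  # perpendicular

        t = np.arange(0.0, reach - disc_r, 1.0)
        lateral = spec.waviness_amplitude * np.sin(
            2 * np.pi * t / spec.waviness_period + phases[i]
        )
        polyline = (
            np.asarray(center)
            + np.outer(disc_r + t, u)
            + np.outer(lateral, v)
        )
        truth = TruthSegment(root_id=i, label=label, polyline=polyline, width=width)
        ledger.segments.append(truth)

        tube = np.zeros((h, w), dtype=bool)
        _stamp_tube(tube, polyline, width)
        vessel |= tube
        value = AV_ARTERY if label == "artery" else AV_VEIN
        av[tube & (av == 0)] = value

        if spec.branch_prob > 0:
            # at most one child per root, spawned partway along, angled off
            if rng.random() < spec.branch_prob:
                split = rng.integers(len(t) // 3, 2 * len(t) // 3)
                branch_theta = theta + rng.choice([-1, 1]) * rng.uniform(0.3, 0.6)
                bu = np.array([np.sin(branch_theta), np.cos(branch_theta)])
                bt = np.arange(0.0, (reach - disc_r) - t[split], 1.0)
                branch_line = polyline[split] + np.outer(bt, bu)
                inside = (
                    (branch_line[:, 0] > spec.width_root)
                    & (branch_line[:, 0] < h - spec.width_root)
                    & (branch_line[:, 1] > spec.width_root)
                    & (branch_line[:, 1] < w - spec.width_root)
                )
                branch_line = branch_line[inside]
                if len(branch_line) > 10:
                    bw = max(spec.width_min, width * spec.width_decay)
                    btube = np.zeros((h, w), dtype=bool)
                    _stamp_tube(btube, branch_line, bw)
                    vessel |= btube
                    av[btube & (av == 0)] = value
                    ledger.segments.append(
                        TruthSegment(root_id=i, label=label, polyline=branch_line, width=bw)
                    )

    # disc and cup as concentric ellipses (slightly taller than wide,
    # as real discs tend to be)
    disc_mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw.ellipse(center[0], center[1], disc_r * 1.0, disc_r * 0.94, shape=(h, w))
    disc_mask[rr, cc] = True
    cup_mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw.ellipse(
        center[0], center[1], disc_r * spec.cup_ratio, disc_r * 0.94 * spec.cup_ratio, shape=(h, w)
    )
    cup_mask[rr, cc] = True

    ledger.vessel_area = int(vessel.sum())
    for mask, attr in ((disc_mask, "disc_extent"), (cup_mask, "cup_extent")):
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        setattr(ledger, attr, (int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1)))

    bundle = SegmentationBundle(
        vessel_mask=vessel,
        av_labels=av,
        disc_mask=disc_mask,
        cup_mask=cup_mask,
        source_id=f"scene_{spec.seed:04d}",
    )
    return bundle, ledger


def match_segment_to_truth(segment, ledger: TruthLedger) -> TruthSegment:
    """The ledger vessel nearest a measured segment's midpoint."""
    mid = segment.points[len(segment.points) // 2].astype(float)
    return min(
        ledger.segments,
        key=lambda t: float(np.linalg.norm(t.polyline - mid, axis=1).min()),
    )


def render_fundus_photo(bundle: SegmentationBundle, margin: int = 40) -> np.ndarray:
    """Paint a crude RGB fundus photograph from a scene's masks.

    A bright orange circular field on black background, darker vessels,
    a pale disc — enough to exercise preprocessing, nothing more.
    """
    h, w = bundle.geometry
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rr, cc = np.ogrid[:h, :w]
    field_r = min(h, w) / 2.0 - margin
    field = ((rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2) <= field_r**2
    rgb[field] = (200, 110, 60)
    if bundle.disc_mask is not None:
        rgb[bundle.disc_mask & field] = (240, 220, 180)
    rgb[bundle.vessel_mask & field] = (120, 40, 30)
    return rgb


def generate_ensemble_draws(
    true_class: str,
    concentration: float,
    n_models: int = 8,
    seed: int = 0,
) -> EnsembleGrades:
    """Draw per-model 3-class probabilities centered on ``true_class``.

    Rows are Dirichlet with parameters ``1 + concentration`` on the
    true class and 1 elsewhere: higher concentration pulls every model
    toward certainty (SD -> 0 as concentration -> inf), low
    concentration produces the disagreement that trips the confidence
    gate.  Deterministic per seed.
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    idx = CLASS_NAMES.index(true_class)
    if np.isinf(concentration):
        probs = np.zeros((n_models, 3))
        probs[:, idx] = 1.0
        return EnsembleGrades(probs=probs)
    rng = np.random.default_rng(seed)
    alpha = np.ones(3)
    alpha[idx] += concentration
    probs = rng.dirichlet(alpha, size=n_models)
    return EnsembleGrades(probs=probs)


def write_demo_dataset(
    out_dir: str | Path,
    n_scenes: int = 5,
    seed: int = 0,
    gradable_concentration: float = 200.0,
    ungradable_every: int = 0,
) -> List[str]:
    """Write a runnable demo dataset: mask bundles, photos, grades, truth.

    Every ``ungradable_every``-th scene (when > 0) gets a low-
    concentration ensemble draw so the confidence gate has something to
    reject.  Returns the scene ids written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    ids, grade_rows, truth_rows = [], [], []
    for i in range(n_scenes):
        spec = TreeSpec(seed=seed + i)
        bundle, ledger = generate_vessel_scene(spec)
        sid = f"scene_{i:03d}"
        bundle.source_id = sid
        write_bundle(bundle, out, stem=sid)
        Image.fromarray(render_fundus_photo(bundle)).save(out / f"{sid}.png")

        low_conf = ungradable_every > 0 and i % ungradable_every == ungradable_every - 1
        if low_conf:
            # a draw that actually trips the default gate: redraw (still
            # deterministic in the seed) until mean < 0.75 or SD > 0.1
            from .quality import aggregate_ensemble

            for attempt in range(50):
                grades = generate_ensemble_draws(
                    "good", 2.0, seed=seed + 1000 + i + 10_000 * attempt
                )
                _, mean, sd = aggregate_ensemble(grades)
                if mean < 0.75 or sd > 0.1:
                    break
        else:
            grades = generate_ensemble_draws(
                "good", gradable_concentration, seed=seed + 1000 + i
            )
        row = {"source_id": sid}
        for m in range(8):
            for c, name in enumerate(CLASS_NAMES):
                row[f"m{m + 1}_{name}"] = grades.probs[m, c]
        grade_rows.append(row)

        for seg in ledger.segments:
            truth_rows.append(
                {
                    "source_id": sid,
                    "root_id": seg.root_id,
                    "label": seg.label,
                    "width": seg.width,
                    "arc_length": seg.arc_length,
                    "chord_length": seg.chord_length,
                }
            )
        ids.append(sid)
    pd.DataFrame(grade_rows).to_csv(out / "grades.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return ids
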