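"""Vascular and optic-disc morphometry.

Implements the feature catalog measured per image and per zone:

* three tortuosity measures — distance tortuosity (arc/chord),
  squared-curvature tortuosity (integral of squared curvature along the
  centerline), and tortuosity density (inflection-partitioned arc/chord
  excess, normalized by length);
* box-counting (Minkowski–Bouligand) fractal dimension;
* vessel density (vessel area over region area) and average caliber;
* vessel caliber summary equivalents CRAE/CRVE and the
  arteriolar–venular ratio (AVR), by both the Hubbard (Parr–Hubbard)
  and the Knudtson revised iterative-pairing formulas, from the six
  widest arteries/veins in each zone;
* optic disc/cup extents and vertical/horizontal cup-to-disc ratios.

Zones follow the standard peripapillary definitions: Zone B is the
annulus 0.5–1.0 disc diameters from the disc margin, Zone C 0.5–2.0.
All calibers are reported in pixels; multiply by a micrometers-per-
pixel scale when the resolution is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .seg_io import (
    AV_ARTERY,
    AV_VEIN,
    DiscGeometry,
    SegmentationBundle,
    disc_geometry,
)
from .vessel_graph import SkeletonGraph, VesselSegment, build_graph

# Knudtson revised-formula branching coefficients
KNUDTSON_ARTERY_K = 0.88
KNUDTSON_VEIN_K = 0.95

#: curvature magnitudes below this (1/px) count as straight when
#: partitioning at inflection points
CURVATURE_SIGN_EPS = 1e-3


class SegmentExcluded(ValueError):
    """A segment does not admit the requested measure (e.g. zero chord)."""


# ---------------------------------------------------------------------------
# zones


@dataclass(frozen=True)
class ZoneSpec:
    """A measurement annulus in units of disc diameters from the disc margin."""

    name: str
    inner_offset: float
    outer_offset: float

    def __post_init__(self) -> None:
        if not self.outer_offset > self.inner_offset >= 0:
            raise ValueError("need outer_offset > inner_offset >= 0")


ZONE_B = ZoneSpec("B", inner_offset=0.5, outer_offset=1.0)
ZONE_C = ZoneSpec("C", inner_offset=0.5, outer_offset=2.0)


def zone_mask(disc: DiscGeometry, zone: ZoneSpec, frame: tuple[int, int]) -> np.ndarray:
    """Rasterize a measurement annulus around the disc, clipped to the frame.

    Inner/outer radii are ``diameter/2 + offset * diameter``; a pixel
    belongs to the annulus when its center lies in [inner, outer).
    """
    d = disc.diameter
    if d <= 0:
        raise ValueError("disc diameter must be positive")
    inner = d / 2.0 + zone.inner_offset * d
    outer = d / 2.0 + zone.outer_offset * d
    rr, cc = np.ogrid[: frame[0], : frame[1]]
    r2 = (rr - disc.center[0]) ** 2 + (cc - disc.center[1]) ** 2
    mask = (r2 >= inner**2) & (r2 < outer**2)
    if not mask.any():
        warnings.warn(f"zone {zone.name} annulus lies entirely outside the frame")
    return mask


# ---------------------------------------------------------------------------
# tortuosity


def _smooth_path(points: np.ndarray, window: int) -> np.ndarray:
    """Moving-average path smoothing, same length out.

    Ends are padded by odd (point-symmetric) reflection, which
    extrapolates the path tangentially: a digital straight line maps to
    itself exactly instead of being pulled inward at the endpoints.
    """
    if window <= 1 or len(points) <= window:
        return points.astype(float)
    pad = window // 2
    padded = np.pad(
        points.astype(float), ((pad, pad), (0, 0)), mode="reflect", reflect_type="odd"
    )
    kernel = np.ones(window) / window
    return np.column_stack(
        [np.convolve(padded[:, i], kernel, mode="valid") for i in range(2)]
    )


def _resample_arclength(points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing."""
    pts = points.astype(float)
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] <= spacing:
        return pts
    si = np.arange(0.0, s[-1] + spacing / 2, spacing)
    return np.column_stack([np.interp(si, s, pts[:, i]) for i in range(2)])


def rectified_arc_length(points: np.ndarray, window: int = 5) -> float:
    """Arc length of a pixel chain, corrected for stair-step inflation.

    Summing per-step lengths (1 axial, sqrt(2) diagonal) over a digital
    curve overestimates the underlying continuous length by up to ~8%
    depending on orientation.  Resampling to unit spacing and smoothing
    with a short moving average removes the staircase while leaving
    genuine curvature (radii well above the window) intact.
    """
    smoothed = _smooth_path(_resample_arclength(points, 1.0), window)
    return float(np.linalg.norm(np.diff(smoothed, axis=0), axis=1).sum())


def distance_tortuosity(segment: VesselSegment) -> float:
    """Arc length over chord length; 1.0 for a straight vessel.

    Uses the rectified (de-staircased) arc length so a digitized
    straight line scores exactly 1 regardless of orientation.
    """
    chord = segment.chord_length
    if chord <= 0:
        raise SegmentExcluded("coincident endpoints: chord length is zero")
    return max(1.0, rectified_arc_length(segment.points) / chord)


def _spline_curvature(points: np.ndarray, residual: float = 0.5):
    """Signed curvature along a smoothing-spline fit of a pixel chain.

    A parametric cubic smoothing spline (residual budget ``residual``
    px^2 per point, absorbing rasterization noise) is fitted over the
    arc-length parameter; curvature comes from its analytic
    derivatives.  Returns (kappa, s, points_on_spline) sampled at unit
    arc-length spacing over the interior knot span.
    """
    from scipy import interpolate

    pts = _resample_arclength(points, 1.0)
    # drop a few px at each tip: skeleton endpoints carry thinning jogs
    # that would otherwise bend the whole fit
    if len(pts) > 30:
        pts = pts[4:-4]
    if len(pts) < 5:
        raise SegmentExcluded("segment too short for curvature")
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(d)])
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], u=u, s=len(pts) * residual, k=3)
    s = np.linspace(u[0], u[-1], max(int(u[-1] - u[0]), 10))
    dr, dc = interpolate.splev(s, tck, der=1)
    d2r, d2c = interpolate.splev(s, tck, der=2)
    r, c = interpolate.splev(s, tck)
    denom = (dr**2 + dc**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, (dc * d2r - dr * d2c) / denom, 0.0)
    # the chain parameter u carries the staircase-inflated digital
    # length; |dq/du| rescales measures to the smooth curve's own arc
    # length (it is < 1 wherever the spline cuts staircase corners)
    speed = np.sqrt(dr**2 + dc**2)
    return kappa, s, np.column_stack([r, c]), speed


def squared_curvature_tortuosity(segment: VesselSegment) -> float:
    """Integral of squared curvature along the smoothed centerline.

    Units 1/px: halving the radius of an arc at fixed angle doubles the
    value.  Unnormalized by default; divide by the arc length for the
    length-normalized variant.
    """
    if segment.n_points < 5:
        raise SegmentExcluded("need >= 5 points for curvature")
    kappa, s, _, speed = _spline_curvature(segment.points)
    return float(np.trapezoid(kappa**2 * speed, s))


def tortuosity_density(segment: VesselSegment) -> float:
    """Inflection-partitioned tortuosity (tortuosity density).

    The centerline is split at inflection points into n maximal
    subsegments of constant curvature sign; the measure is
    ``((n - 1) / n) * (1 / L) * sum_i (arc_i / chord_i - 1)`` with L the
    total arc length.  A straight vessel or a single smooth arc scores
    0; each additional twist adds its arc/chord excess.  Curvature
    magnitudes below :data:`CURVATURE_SIGN_EPS` count as straight when
    locating inflections.
    """
    if segment.n_points < 5:
        raise SegmentExcluded("need >= 5 points for curvature")
    kappa, s, pts, _ = _spline_curvature(segment.points)
    # normalize by the smooth curve's length, not the inflated digital one
    total = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if total <= 0:
        return 0.0
    signs = np.where(np.abs(kappa) < CURVATURE_SIGN_EPS, 0, np.sign(kappa)).astype(int)

    # runs of constant nonzero sign; zeros extend the current run
    boundaries: List[int] = [0]
    current = 0
    for i, sg in enumerate(signs):
        if sg == 0:
            continue
        if current == 0:
            current = sg
        elif sg != current:
            boundaries.append(i)
            current = sg
    boundaries.append(len(pts) - 1)

    # hysteresis: a sign run shorter than min_run_arc px is curvature
    # flicker, not a real twist — merge it into its neighbour, otherwise
    # spurious boundaries split humps and understate their arc excess
    min_run_arc = 5.0
    ds = float(s[1] - s[0]) if len(s) > 1 else 1.0
    merged = [boundaries[0]]
    for b in boundaries[1:-1]:
        if (b - merged[-1]) * ds >= min_run_arc:
            merged.append(b)
    merged.append(boundaries[-1])
    boundaries = merged

    n = len(boundaries) - 1
    if n <= 1:
        return 0.0
    excess = 0.0
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        sub = pts[a : b + 1]
        if len(sub) < 2:
            continue
        arc = float(np.linalg.norm(np.diff(sub, axis=0), axis=1).sum())
        chord = float(np.linalg.norm(sub[-1] - sub[0]))
        if chord > 0:
            excess += arc / chord - 1.0
    return float((n - 1) / n / total * excess)


# ---------------------------------------------------------------------------
# mask-level features


def fractal_dimension(mask: np.ndarray, return_r2: bool = False):
    """Box-counting (Minkowski–Bouligand) fractal dimension.

    Occupied boxes are counted over a dyadic ladder of box sizes from
    2 px to a quarter of the short frame side; the dimension is the
    least-squares slope of log N(eps) against log(1/eps), clamped to
    the planar range [0, 2].  With ``return_r2`` the fit's R^2 is also
    returned as a quality diagnostic.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no fractal dimension")
    short = min(mask.shape)
    sizes = []
    size = 2
    while size <= max(short // 4, 2):
        sizes.append(size)
        size *= 2
    counts = []
    for eps in sizes:
        pad_r = (-mask.shape[0]) % eps
        pad_c = (-mask.shape[1]) % eps
        padded = np.pad(mask, ((0, pad_r), (0, pad_c)))
        blocks = padded.reshape(
            padded.shape[0] // eps, eps, padded.shape[1] // eps, eps
        ).any(axis=(1, 3))
        counts.append(blocks.sum())
    log_inv_eps = -np.log(np.asarray(sizes, dtype=float))
    log_n = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(log_inv_eps, log_n, 1)
    fd = float(np.clip(slope, 0.0, 2.0))
    if not return_r2:
        return fd
    pred = slope * log_inv_eps + intercept
    ss_res = float(((log_n - pred) ** 2).sum())
    ss_tot = float(((log_n - log_n.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return fd, r2


def vessel_density(mask: np.ndarray, region: Optional[np.ndarray] = None) -> float:
    """Fraction of the region covered by vessel (whole frame by default)."""
    mask = np.asarray(mask, dtype=bool)
    if region is None:
        region = np.ones_like(mask)
    region = np.asarray(region, dtype=bool)
    if region.shape != mask.shape:
        raise ValueError("mask and region geometry differ")
    area = int(region.sum())
    if area == 0:
        raise ValueError("empty region")
    return int((mask & region).sum()) / area


# ---------------------------------------------------------------------------
# caliber equivalents


@dataclass
class CaliberSelection:
    """The widths feeding a caliber equivalent, with a quality flag."""

    widths: List[float]
    segment_ids: List[int]
    complete: bool  # False when fewer than the requested count existed


def select_six_widest(
    segments: Sequence[VesselSegment],
    label: str,
    zone: Optional[np.ndarray] = None,
    count: int = 6,
    min_zone_points: int = 5,
) -> CaliberSelection:
    """Pick the ``count`` widest segments of a label inside a zone.

    A segment qualifies when at least ``min_zone_points`` of its
    centerline points fall inside the annulus (radial trunks cross a
    zone rather than lying within it, so membership is by presence,
    not by fraction of length); its caliber is the mean width over the
    in-zone points only.  Ranking is by caliber descending, ties broken
    by longer arc length then by segment id.  When fewer than ``count``
    qualify, all are returned and the selection is flagged incomplete —
    widths are never fabricated.
    """
    ranked = []
    for seg in segments:
        if seg.label != label or seg.widths is None:
            continue
        if zone is not None:
            inside = zone[seg.points[:, 0], seg.points[:, 1]]
            if inside.sum() < min_zone_points:
                continue
            widths = seg.widths[inside]
        else:
            widths = seg.widths
        if len(widths) == 0:
            continue
        ranked.append((float(np.mean(widths)), seg.arc_length, seg.segment_id))
    ranked.sort(key=lambda t: (-t[0], -t[1], t[2]))
    top = ranked[:count]
    return CaliberSelection(
        widths=[w for w, _, _ in top],
        segment_ids=[sid for _, _, sid in top],
        complete=len(ranked) >= count,
    )


def _pair_once(widths: Sequence[float], combine) -> List[float]:
    """One round of pairing: largest with smallest, odd middle carried."""
    w = sorted(widths, reverse=True)
    out: List[float] = []
    i, j = 0, len(w) - 1
    while i < j:
        out.append(combine(w[i], w[j]))
        i += 1
        j -= 1
    if i == j:
        out.append(w[i])
    return out


def _iterative_pairing(widths: Sequence[float], combine) -> float:
    w = [float(x) for x in widths]
    if not w:
        raise ValueError("empty width list")
    if any(x <= 0 for x in w):
        raise ValueError("widths must be positive")
    while len(w) > 1:
        w = _pair_once(w, combine)
    return w[0]


def caliber_knudtson(widths: Sequence[float], vessel_type: str) -> float:
    """Revised (Knudtson) caliber equivalent by iterative pairing.

    Branches combine as ``W = k * sqrt(Wa^2 + Wb^2)`` with k = 0.88 for
    arteries and 0.95 for veins; widths are sorted and the largest is
    paired with the smallest each round, any odd middle value carried,
    until a single equivalent (CRAE/CRVE) remains.  Scale-invariant, so
    pixel widths are fine.
    """
    k = {"artery": KNUDTSON_ARTERY_K, "vein": KNUDTSON_VEIN_K}[vessel_type]
    return _iterative_pairing(widths, lambda a, b: k * np.hypot(a, b))


def caliber_hubbard(widths: Sequence[float], vessel_type: str) -> float:
    """Parr–Hubbard caliber equivalent by iterative pairing.

    Branch formulas (Wa the wider, Wb the narrower of a pair):

    * artery: ``sqrt(0.87 Wa^2 + 1.01 Wb^2 - 0.22 Wa Wb - 10.76)``
    * vein:   ``sqrt(0.72 Wa^2 + 0.91 Wb^2 + 450.05)``

    The additive constants were calibrated in micrometers; when widths
    are pixels their relative weight depends on the (unknown) image
    resolution, so pixel-unit Hubbard equivalents are comparable only
    within a fixed acquisition setup.  A pair whose artery radicand is
    negative (tiny arteriolar widths) is rejected with a diagnostic.
    """

    def artery(a: float, b: float) -> float:
        wa, wb = max(a, b), min(a, b)
        radicand = 0.87 * wa**2 + 1.01 * wb**2 - 0.22 * wa * wb - 10.76
        if radicand < 0:
            raise ValueError(
                f"negative radicand for artery pair ({wa:.3g}, {wb:.3g}): "
                "widths too small for the Hubbard formula"
            )
        return float(np.sqrt(radicand))

    def vein(a: float, b: float) -> float:
        wa, wb = max(a, b), min(a, b)
        return float(np.sqrt(0.72 * wa**2 + 0.91 * wb**2 + 450.05))

    combine = {"artery": artery, "vein": vein}[vessel_type]
    w = [float(x) for x in widths]
    if not w:
        raise ValueError("empty width list")
    while len(w) > 1:
        w = _pair_once(w, combine)
    return w[0]


def avr(crae: float, crve: float) -> float:
    """Arteriolar-to-venular ratio CRAE / CRVE."""
    if crve <= 0:
        raise ValueError("CRVE must be positive")
    return crae / crve


# ---------------------------------------------------------------------------
# disc / cup


def disc_cup_metrics(
    disc_mask: np.ndarray, cup_mask: Optional[np.ndarray] = None
) -> Dict[str, Optional[float]]:
    """Bounding-box extents of disc and cup plus cup-to-disc ratios.

    Vertical CDR = cup height / disc height; horizontal likewise.  An
    empty or absent cup reports the disc extents with missing CDRs.
    """
    disc = disc_geometry(disc_mask)
    out: Dict[str, Optional[float]] = {
        "disc_height": float(disc.height),
        "disc_width": float(disc.width),
        "cup_height": None,
        "cup_width": None,
        "vertical_CDR": None,
        "horizontal_CDR": None,
    }
    if cup_mask is not None and np.asarray(cup_mask, bool).any():
        cup = disc_geometry(cup_mask)
        out["cup_height"] = float(cup.height)
        out["cup_width"] = float(cup.width)
        out["vertical_CDR"] = cup.height / disc.height
        out["horizontal_CDR"] = cup.width / disc.width
    return out


# ---------------------------------------------------------------------------
# whole-image measurement


#: feature columns of one record, in emission order
FEATURE_COLUMNS: List[str] = (
    [
        f"{feat}_{zone}"
        for zone in ("whole", "zoneB", "zoneC")
        for feat in (
            "distance_tortuosity",
            "squared_curvature_tortuosity",
            "tortuosity_density",
            "fractal_dimension",
            "vessel_density",
            "average_width",
        )
    ]
    + [
        f"{feat}_{zone}"
        for zone in ("zoneB", "zoneC")
        for feat in (
            "CRAE_hubbard",
            "CRVE_hubbard",
            "AVR_hubbard",
            "CRAE_knudtson",
            "CRVE_knudtson",
            "AVR_knudtson",
        )
    ]
    + [
        "disc_height",
        "disc_width",
        "cup_height",
        "cup_width",
        "vertical_CDR",
        "horizontal_CDR",
    ]
)


@dataclass
class FeatureRecord:
    """One image's feature vector — the CSV row the pipeline emits."""

    source_id: str
    values: Dict[str, Optional[float]] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {"source_id": self.source_id}
        for col in FEATURE_COLUMNS:
            row[col] = self.values.get(col)
        row["flags"] = ";".join(self.flags)
        return row


def _label_segments(graph: SkeletonGraph, av_labels: Optional[np.ndarray]) -> None:
    """Assign artery/vein labels by majority vote along each centerline."""
    if av_labels is None:
        return
    for seg in graph.segments:
        vals = av_labels[seg.points[:, 0], seg.points[:, 1]]
        n_a = int((vals == AV_ARTERY).sum())
        n_v = int((vals == AV_VEIN).sum())
        if n_a == n_v == 0:
            seg.label = "unknown"
        else:
            seg.label = "artery" if n_a >= n_v else "vein"


def _clip_to_zone(
    segments: Sequence[VesselSegment], zone: np.ndarray, min_points: int = 10
) -> List[VesselSegment]:
    """Sub-segments formed by the maximal in-zone runs of each centerline.

    Zone-restricted features use exactly the centerline inside the
    annulus: each maximal run of consecutive in-zone points (of at
    least ``min_points``) becomes its own segment, inheriting label
    and widths.
    """
    clipped: List[VesselSegment] = []
    for seg in segments:
        inside = zone[seg.points[:, 0], seg.points[:, 1]]
        run_start = None
        for i, flag in enumerate(np.append(inside, False)):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                if i - run_start >= min_points:
                    clipped.append(
                        VesselSegment(
                            points=seg.points[run_start:i],
                            widths=None if seg.widths is None else seg.widths[run_start:i],
                            label=seg.label,
                            segment_id=seg.segment_id,
                        )
                    )
                run_start = None
    return clipped


def _tortuosity_block(
    segments: Sequence[VesselSegment], zone: Optional[np.ndarray]
) -> Dict[str, Optional[float]]:
    """Arc-length-weighted mean tortuosities over qualifying segments."""
    if zone is not None:
        segments = _clip_to_zone(segments, zone)
    acc = {"distance_tortuosity": [], "squared_curvature_tortuosity": [], "tortuosity_density": []}
    weights = {k: [] for k in acc}
    for seg in segments:
        for name, fn in (
            ("distance_tortuosity", distance_tortuosity),
            ("squared_curvature_tortuosity", squared_curvature_tortuosity),
            ("tortuosity_density", tortuosity_density),
        ):
            try:
                value = fn(seg)
            except SegmentExcluded:
                continue
            acc[name].append(value)
            weights[name].append(seg.arc_length)
    out: Dict[str, Optional[float]] = {}
    for name, vals in acc.items():
        if vals:
            out[name] = float(np.average(vals, weights=weights[name]))
        else:
            out[name] = None
    return out


def _caliber_block(
    segments: Sequence[VesselSegment], zone: np.ndarray, record: FeatureRecord, zone_name: str
) -> Dict[str, Optional[float]]:
    out: Dict[str, Optional[float]] = {}
    selections = {}
    for label in ("artery", "vein"):
        sel = select_six_widest(segments, label, zone)
        selections[label] = sel
        if sel.widths and not sel.complete:
            record.flags.append(f"fewer_than_6_{label}_{zone_name}")
    for method, fn in (("hubbard", caliber_hubbard), ("knudtson", caliber_knudtson)):
        crae = crve = None
        try:
            if selections["artery"].widths:
                crae = fn(selections["artery"].widths, "artery")
        except ValueError as exc:
            record.flags.append(f"CRAE_{method}_{zone_name}_failed:{exc}")
        try:
            if selections["vein"].widths:
                crve = fn(selections["vein"].widths, "vein")
        except ValueError as exc:
            record.flags.append(f"CRVE_{method}_{zone_name}_failed:{exc}")
        out[f"CRAE_{method}"] = crae
        out[f"CRVE_{method}"] = crve
        out[f"AVR_{method}"] = avr(crae, crve) if crae and crve else None
    return out


def measure_image(
    bundle: SegmentationBundle,
    graph: Optional[SkeletonGraph] = None,
    spur_min_length: float = 10.0,
) -> FeatureRecord:
    """Compute the full feature record for one segmented image.

    Whole-image features are always attempted; Zone B/C features need a
    disc, caliber additionally needs artery/vein labels.  Pixel-level
    features (density, fractal dimension, average width) use the vessel
    mask clipped to the zone; segment-level tortuosities use segments
    with at least half their centerline inside the zone.  Failures
    degrade to missing values — a record is always returned.
    """
    record = FeatureRecord(source_id=bundle.source_id)
    vessel = bundle.vessel_mask
    frame = bundle.geometry

    if graph is None and vessel.any():
        graph = build_graph(vessel, spur_min_length=spur_min_length)
    if graph is not None:
        _label_segments(graph, bundle.av_labels)
    segments = graph.segments if graph is not None else []

    regions: Dict[str, Optional[np.ndarray]] = {"whole": None}
    disc: Optional[DiscGeometry] = None
    if bundle.disc_mask is not None and bundle.disc_mask.any():
        disc = disc_geometry(bundle.disc_mask)
        regions["zoneB"] = zone_mask(disc, ZONE_B, frame)
        regions["zoneC"] = zone_mask(disc, ZONE_C, frame)
        record.values.update(disc_cup_metrics(bundle.disc_mask, bundle.cup_mask))
    else:
        record.flags.append("no_disc")

    for zone_name, region in regions.items():
        if vessel.any():
            clipped = vessel if region is None else (vessel & region)
            record.values[f"vessel_density_{zone_name}"] = vessel_density(vessel, region)
            if clipped.any():
                record.values[f"fractal_dimension_{zone_name}"] = fractal_dimension(clipped)
            widths = []
            for seg in segments:
                if seg.widths is None:
                    continue
                if region is None:
                    widths.append(seg.widths)
                else:
                    widths.append(seg.widths[region[seg.points[:, 0], seg.points[:, 1]]])
            widths = np.concatenate(widths) if widths else np.array([])
            if widths.size:
                record.values[f"average_width_{zone_name}"] = float(widths.mean())
            for name, value in _tortuosity_block(segments, region).items():
                record.values[f"{name}_{zone_name}"] = value
        if zone_name != "whole" and bundle.av_labels is not None and region is not None:
            record.values.update(
                {
                    f"{k}_{zone_name}": v
                    for k, v in _caliber_block(segments, region, record, zone_name).items()
                }
            )
    if not vessel.any():
        record.flags.append("empty_vessel_mask")
    return record
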