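"""End-to-end batch pipeline: crop, gate, measure, report.

Runs over a directory of images and/or precomputed segmentation-map
bundles with no human intervention.  Segmentation itself is *ingested*,
not computed: the pipeline reads probability maps or discrete masks
produced elsewhere (or by :mod:`retimorph.synthetic`); an external
predictor can be plugged in by writing its outputs in the same layout.

Expected input layout (per image id)::

    <id>.png            optional fundus photograph
    <id>_vessel.png     binary vessel mask (required to measure)
    <id>_av.png         artery/vein palette map (optional)
    <id>_disc.png       optic disc mask (optional)
    <id>_cup.png        optic cup mask (optional)
    grades.csv          ensemble quality probabilities (optional)

Images whose final quality decision is ungradable are excluded from
feature measurement.  Failures are isolated per image: one bad file
never aborts the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List

import pandas as pd

from . import preprocess, quality, seg_io
from .morphometry import FEATURE_COLUMNS, measure_image
from .quality import GateConfig, QualityDecision

logger = logging.getLogger("retimorph")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    gate: GateConfig = field(default_factory=GateConfig)
    intensity_threshold: int = 10
    spur_min_length: float = 10.0
    mode: str = "full"  # full | features-only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("full", "features-only"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RunSummary:
    config: PipelineConfig
    processed: List[str] = field(default_factory=list)
    gated_out: List[str] = field(default_factory=list)
    failed: Dict[str, str] = field(default_factory=dict)
    feature_rows: List[Dict[str, object]] = field(default_factory=list)
    decisions: Dict[str, QualityDecision] = field(default_factory=dict)
    crops: List[tuple[str, preprocess.CropRecord]] = field(default_factory=list)
    timings: Dict[str, float] = field(default_factory=dict)


def discover_ids(input_dir: Path) -> List[str]:
    """Image ids present in a directory, from vessel masks or photos."""
    ids = {p.name[: -len("_vessel.png")] for p in input_dir.glob("*_vessel.png")}
    suffixes = ("_vessel", "_av", "_disc", "_cup")
    for p in input_dir.glob("*.png"):
        if not any(p.stem.endswith(s) for s in suffixes):
            ids.add(p.stem)
    return sorted(ids)


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Process every image in the input directory; never raises per-image.

    Stage order per id: preprocess (photo present, full mode) ->
    quality gate (grades present) -> mask ingestion -> morphometry.
    Gated-out images get no feature row.
    """
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory {input_dir} does not exist")
    ids = discover_ids(input_dir)
    if not ids:
        raise FileNotFoundError(f"no images or mask bundles found in {input_dir}")

    summary = RunSummary(config=config)
    grades_path = input_dir / "grades.csv"
    grades = quality.read_grades_csv(grades_path) if grades_path.exists() else {}

    for sid in ids:
        t0 = time.perf_counter()
        try:
            if config.mode == "full":
                photo = input_dir / f"{sid}.png"
                if photo.exists() and not photo.stem.endswith(
                    ("_vessel", "_av", "_disc", "_cup")
                ):
                    image = preprocess.load_image(photo, source_id=sid)
                    cropped = preprocess.preprocess_image(
                        image, intensity_threshold=config.intensity_threshold
                    )
                    out_dir = Path(config.output_dir) / "crops"
                    out_dir.mkdir(parents=True, exist_ok=True)
                    preprocess.save_image(cropped, out_dir / f"{sid}.png")
                    summary.crops.append((sid, cropped.crop))

            if sid in grades:
                decision = quality.grade_image(grades[sid], config.gate)
                summary.decisions[sid] = decision
                if decision.final_class == quality.UNGRADABLE:
                    summary.gated_out.append(sid)
                    continue

            if (input_dir / f"{sid}_vessel.png").exists():
                bundle = seg_io.read_bundle(input_dir, sid)
                record = measure_image(bundle, spur_min_length=config.spur_min_length)
                summary.feature_rows.append(record.to_row())
                summary.processed.append(sid)
        except Exception as exc:  # per-image isolation
            logger.exception("failed on %s", sid)
            summary.failed[sid] = f"{type(exc).__name__}: {exc}"
        finally:
            summary.timings[sid] = time.perf_counter() - t0
    return summary


def emit_reports(summary: RunSummary, output_dir: str | Path | None = None) -> Dict[str, Path]:
    """Write feature/quality/failure CSVs and a run log; return their paths.

    The feature CSV is byte-deterministic for identical inputs, config,
    and seed (timings go to the log only).
    """
    out = Path(output_dir or summary.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    features = pd.DataFrame(
        summary.feature_rows, columns=["source_id", *FEATURE_COLUMNS, "flags"]
    )
    paths["features"] = out / "features.csv"
    features.to_csv(paths["features"], index=False, float_format="%.6f")

    if summary.decisions:
        paths["quality"] = out / "quality.csv"
        quality.write_decisions_csv(summary.decisions, paths["quality"])
    if summary.failed:
        paths["failures"] = out / "failures.csv"
        pd.DataFrame(
            [{"source_id": k, "error": v} for k, v in sorted(summary.failed.items())]
        ).to_csv(paths["failures"], index=False)
    if summary.crops:
        paths["crops"] = out / "crop_records.csv"
        preprocess.write_crop_records(summary.crops, paths["crops"])

    paths["log"] = out / "run.log"
    with open(paths["log"], "w") as fh:
        cfg = asdict(summary.config)
        fh.write("config: " + json.dumps(cfg, default=str) + "\n")
        fh.write(
            f"processed={len(summary.processed)} gated_out={len(summary.gated_out)} "
            f"failed={len(summary.failed)}\n"
        )
        for sid, dt in sorted(summary.timings.items()):
            fh.write(f"{sid}: {dt:.3f}s\n")
    return paths
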