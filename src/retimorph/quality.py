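"""Ensemble image-quality gating.

Image quality is predicted by an ensemble of classifiers, each emitting
a 3-class probability vector over (good, usable, reject).  Good and
usable collapse to *gradable*, reject to *ungradable*.  The ensemble's
mean confidence and between-model standard deviation drive a
confidence gate: a gradable prediction whose mean probability is below
``mean_threshold`` or whose SD exceeds ``sd_threshold`` is rectified to
ungradable, suppressing false-gradable images before they reach
segmentation and feature measurement.

The classifier itself is pluggable: anything mapping an image to a
3-vector can feed :class:`EnsembleGrades`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

CLASS_NAMES = ("good", "usable", "reject")
GRADABLE = "gradable"
UNGRADABLE = "ungradable"

#: class probability columns expected in a grades CSV, m1_good .. m8_reject
GRADES_CSV_COLUMNS = [
    f"m{m}_{c}" for m in range(1, 9) for c in CLASS_NAMES
]


@dataclass(frozen=True)
class GateConfig:
    """Confidence-gate thresholds (defaults: mean 0.75, SD 0.1)."""

    mean_threshold: float = 0.75
    sd_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.mean_threshold < 1 and 0 < self.sd_threshold < 1):
            raise ValueError("gate thresholds must lie in (0, 1)")


@dataclass
class EnsembleGrades:
    """Per-model 3-class quality probabilities for one image.

    ``probs`` is (n_models, 3) with columns (good, usable, reject);
    each row must sum to 1 within 1e-6.
    """

    probs: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("probs must be an (n_models, 3) matrix")
        if p.shape[0] < 2:
            raise ValueError("need at least 2 models (SD undefined otherwise)")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        sums = p.sum(axis=1)
        if np.abs(sums - 1).max() > 1e-6:
            raise ValueError("each row of probs must sum to 1")
        self.probs = p

    @property
    def n_models(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class QualityDecision:
    raw_class: str  # good / usable / reject
    binary_class: str  # gradable / ungradable, pre-gate
    mean_confidence: float
    sd_confidence: float
    rectified: bool
    final_class: str = field(default=UNGRADABLE)

    def __post_init__(self) -> None:
        if self.rectified and self.final_class != UNGRADABLE:
            raise ValueError("a rectified decision must be ungradable")


def collapse_to_binary(probs_row: np.ndarray) -> tuple[str, float]:
    """Collapse a 3-class probability row to (binary class, P(gradable)).

    P(gradable) = P(good) + P(usable); P(ungradable) = P(reject).
    The class with the larger probability wins; an exact tie is
    resolved conservatively to ungradable.
    """
    row = np.asarray(probs_row, dtype=float)
    if row.shape != (3,):
        raise ValueError("expected a 3-vector")
    if (row < 0).any():
        raise ValueError("negative probability")
    gradable_p = float(row[0] + row[1])
    binary = GRADABLE if gradable_p > row[2] else UNGRADABLE
    return binary, gradable_p


def aggregate_ensemble(grades: EnsembleGrades) -> tuple[str, float, float]:
    """Combine per-model predictions into (class, mean, SD).

    Each model votes with its collapsed binary class; the majority wins
    (tie -> ungradable).  Mean and SD are then taken over the eight
    per-model probabilities of the *predicted* class.  SD is the
    population standard deviation (divide by n).
    """
    binary = [collapse_to_binary(row) for row in grades.probs]
    votes_gradable = sum(1 for cls, _ in binary if cls == GRADABLE)
    predicted = GRADABLE if votes_gradable > grades.n_models / 2 else UNGRADABLE
    p_gradable = np.array([p for _, p in binary])
    p_pred = p_gradable if predicted == GRADABLE else 1.0 - p_gradable
    return predicted, float(p_pred.mean()), float(p_pred.std(ddof=0))


def apply_confidence_gate(
    predicted: str,
    mean_confidence: float,
    sd_confidence: float,
    config: GateConfig = GateConfig(),
) -> tuple[str, bool]:
    """Rectify low-confidence gradable predictions to ungradable.

    Returns (final class, rectified flag).  Ungradable inputs pass
    through unrectified; rectification only ever moves gradable to
    ungradable.
    """
    if not (0 <= mean_confidence <= 1 and 0 <= sd_confidence <= 1):
        raise ValueError("confidence statistics must lie in [0, 1]")
    if predicted == GRADABLE and (
        mean_confidence < config.mean_threshold or sd_confidence > config.sd_threshold
    ):
        return UNGRADABLE, True
    return predicted, False


def grade_image(grades: EnsembleGrades, config: GateConfig = GateConfig()) -> QualityDecision:
    """Full decision for one image: aggregate the ensemble, then gate.

    ``raw_class`` is chosen consistently with the binary prediction:
    the better of good/usable (by mean probability) when gradable,
    reject when ungradable.
    """
    predicted, mean_c, sd_c = aggregate_ensemble(grades)
    mean3 = grades.probs.mean(axis=0)
    if predicted == GRADABLE:
        raw = CLASS_NAMES[int(np.argmax(mean3[:2]))]
    else:
        raw = "reject"
    final, rectified = apply_confidence_gate(predicted, mean_c, sd_c, config)
    return QualityDecision(
        raw_class=raw,
        binary_class=predicted,
        mean_confidence=mean_c,
        sd_confidence=sd_c,
        rectified=rectified,
        final_class=final,
    )


def read_grades_csv(path: str | Path) -> Dict[str, EnsembleGrades]:
    """Read per-image ensemble probabilities (source_id + 24 columns)."""
    df = pd.read_csv(path)
    missing = [c for c in ["source_id", *GRADES_CSV_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"grades CSV missing columns: {missing}")
    out: Dict[str, EnsembleGrades] = {}
    for _, row in df.iterrows():
        probs = row[GRADES_CSV_COLUMNS].to_numpy(dtype=float).reshape(8, 3)
        sid = str(row["source_id"])
        out[sid] = EnsembleGrades(probs=probs, source_id=sid)
    return out


def write_decisions_csv(decisions: Dict[str, QualityDecision], path: str | Path) -> None:
    rows = [
        {
            "source_id": sid,
            "raw_class": d.raw_class,
            "mean": d.mean_confidence,
            "sd": d.sd_confidence,
            "rectified": d.rectified,
            "final_class": d.final_class,
        }
        for sid, d in sorted(decisions.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
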