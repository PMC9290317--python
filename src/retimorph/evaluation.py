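"""Evaluation statistics: classification, segmentation overlap, agreement.

Classification metrics follow the usual confusion-count formulas, with
undefined (zero-denominator) metrics reported as missing rather than
zero.  Segmentation overlap uses intersection-over-union.  Method
agreement between two sets of measurements uses Bland–Altman mean
difference with 95% limits of agreement, and the intraclass
correlation coefficient (two-way model, absolute agreement, single
measurement) with its 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("empty confusion matrix")


@dataclass
class AgreementResult:
    """Agreement between two measurement methods on paired data."""

    mean_difference: Optional[float] = None
    loa_low: Optional[float] = None
    loa_high: Optional[float] = None
    icc: Optional[float] = None
    icc_ci: Optional[tuple[float, float]] = None


def classification_metrics(c: ConfusionCounts) -> Dict[str, Optional[float]]:
    """Sensitivity, specificity, precision, accuracy, F1 from counts.

    A metric whose denominator is zero is reported as ``None``.
    """

    def _ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    sens = _ratio(c.TP, c.TP + c.FN)
    spec = _ratio(c.TN, c.TN + c.FP)
    prec = _ratio(c.TP, c.TP + c.FP)
    acc = _ratio(c.TP + c.TN, c.TP + c.TN + c.FP + c.FN)
    f1: Optional[float] = None
    if sens is not None and prec is not None:
        f1 = 0.0 if sens + prec == 0 else 2 * sens * prec / (sens + prec)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f1": f1,
    }


def confusion_from_labels(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    """Confusion counts from binary label vectors (1 = positive class)."""
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        TP=int((t & p).sum()),
        TN=int((~t & ~p).sum()),
        FP=int((~t & p).sum()),
        FN=int((t & ~p).sum()),
    )


def row_normalized_confusion(c: ConfusionCounts) -> np.ndarray:
    """2x2 confusion matrix normalized within each true-class row."""
    m = np.array([[c.TN, c.FP], [c.FN, c.TP]], dtype=float)
    sums = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(sums > 0, m / sums, np.nan)


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.  ``labels`` are 1 for the
    positive class; pass ungradable/vessel/disc indicators according
    to the task's positive-class convention.
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (both empty -> 1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask geometry differs")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Mean difference and 95% limits of agreement for paired data.

    Differences d = x - y; limits are mean(d) +/- 1.96 * SD(d) with the
    sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(mean_difference=md, loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd)


def icc(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Intraclass correlation between two fixed raters on the same targets.

    Two-way model, absolute agreement, single measurement (ICC2 in the
    Shrout–Fleiss numbering; identical arithmetic for the random- and
    mixed-effects flavors), with the standard F-based 95% confidence
    interval.  When both raters have zero variance the ICC is
    undefined and reported as missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 paired measurements")
    if np.var(x) == 0 and np.var(y) == 0:
        return AgreementResult(icc=None, icc_ci=None)

    import pingouin as pg

    frame = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["x", "y"], n),
            "score": np.concatenate([x, y]),
        }
    )
    table = pg.intraclass_corr(
        data=frame, targets="target", raters="rater", ratings="score"
    )
    table = table.set_index("Type")
    # pingouin labels the absolute-agreement single-rater row ICC(A,1)
    # (older releases: ICC2); the CI column name moved as well
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[key]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    ci_vals = [float(v) for v in row[ci_col]]
    ci = None if any(np.isnan(ci_vals)) else (ci_vals[0], ci_vals[1])
    value = float(row["ICC"])
    return AgreementResult(icc=None if np.isnan(value) else value, icc_ci=ci)


def agreement(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Bland–Altman and ICC in one result."""
    ba = bland_altman(x, y)
    ic = icc(x, y)
    ba.icc = ic.icc
    ba.icc_ci = ic.icc_ci
    return ba
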