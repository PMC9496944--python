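"""ROC/AUC evaluation, Youden-index cutpoints, and the global threshold.

Scores (TMB or P-TMB) are evaluated against the binary response label with
responders as the positive class and the classification rule
``score > threshold  =>  predicted responder`` (strict inequality).  Each
cohort contributes one Youden-index cutoff; the global threshold is the
arithmetic mean of the per-cohort cutoffs (optionally sample-size
weighted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dataclasses import dataclass
from typing import Sequence

from .exceptions import ParameterError, ValidationError

__all__ = [
    "ROCResult",
    "CutpointResult",
    "roc_curve",
    "youden_cutpoint",
    "global_threshold",
    "classify_by_threshold",
]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    youden_j: float


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ParameterError("scores and labels must have equal length")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValidationError("both classes must be present")
    return s, y


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus -inf and +inf."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def roc_curve(scores, labels) -> ROCResult:
    """ROC over all candidate thresholds; AUC by the trapezoidal rule.

    ``labels``: 1 = responder (positive class).  Thresholds sit at midpoints
    between distinct sorted scores plus +-inf; tied scores move sensitivity
    and specificity simultaneously (diagonal ROC segments).
    """
    s, y = _check_binary(scores, labels)
    thresholds = _candidate_thresholds(s)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    sens = np.array([((s > t) & (y == 1)).sum() / n_pos for t in thresholds])
    spec = np.array([((s <= t) & (y == 0)).sum() / n_neg for t in thresholds])
    # integrate sensitivity over false-positive rate (1 - specificity)
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ties in FPR traverse in rising sensitivity
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCResult(thresholds, sens, spec, auc)


def youden_cutpoint(scores, labels) -> CutpointResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the ROC thresholds (midpoints between adjacent distinct
    scores plus +-inf); ties among maxima are broken toward the smallest
    cutoff.
    """
    roc = roc_curve(scores, labels)
    j = roc.sensitivities + roc.specificities - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[0]
    return CutpointResult(float(roc.thresholds[best]), float(j[best]))


def global_threshold(cutoffs: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Cross-cohort threshold: unweighted (default) or weighted mean."""
    c = np.asarray(cutoffs, dtype=float)
    if c.size == 0:
        raise ParameterError("need at least one per-cohort cutoff")
    if weights is None:
        return float(c.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != c.shape:
        raise ParameterError("weights must match cutoffs in length")
    return float(np.average(c, weights=w))


def classify_by_threshold(scores, threshold: float, labels=None):
    """Predict responder iff score > threshold (strict).

    Returns the 0/1 prediction vector; with ``labels`` also a confusion
    DataFrame with tp/fp/tn/fn counts.
    """
    s = np.asarray(scores, dtype=float)
    pred = (s > threshold).astype(int)
    if labels is None:
        return pred
    y = np.asarray(labels, dtype=int)
    if y.shape != s.shape:
        raise ParameterError("scores and labels must have equal length")
    confusion = pd.DataFrame(
        {
            "tp": [int(((pred == 1) & (y == 1)).sum())],
            "fp": [int(((pred == 1) & (y == 0)).sum())],
            "tn": [int(((pred == 0) & (y == 0)).sum())],
            "fn": [int(((pred == 0) & (y == 1)).sum())],
        }
    )
    return pred, confusion
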