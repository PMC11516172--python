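"""Model validation: AUC, TSS-optimal thresholding, binarization.

The true skill statistic TSS = sensitivity + specificity - 1 is maximized
over candidate thresholds to convert a probability map into a binary
risk/suitability map; the report carries the threshold together with the
rates at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .grid_io import GridValidationError, RasterGrid


@dataclass
class ValidationReport:
    """Validation metrics at a chosen threshold (rates as fractions in [0,1])."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    tss: float
    correct_classification: float
    misclassification: float
    tag: str = ""

    def as_dict(self) -> dict:
        return {
            "tag": self.tag, "auc": self.auc, "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "tss": self.tss, "correct_classification": self.correct_classification,
            "misclassification": self.misclassification,
        }


def _check_two_classes(labels: np.ndarray) -> None:
    if not ((labels == 1).any() and (labels == 0).any()):
        raise GridValidationError("both classes (0 and 1) must be present")


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def _rates_at(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    sens = pred[pos].mean()
    spec = (~pred[neg]).mean()
    return float(sens), float(spec)


def tss_threshold(scores, labels, tag: str = "") -> tuple[float, ValidationReport]:
    """Find the threshold maximizing TSS and report metrics at it.

    Candidates are the midpoints of consecutive sorted unique scores (the
    exact optimum lies at one of them under the `score >= threshold`
    convention).  Ties go to the smallest threshold, i.e. the larger
    predicted-positive area — the conservative choice when positives are
    fires or habitat.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise GridValidationError("all scores identical: no informative threshold")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    # vectorized: sensitivity and specificity for all candidates at once
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] < candidates[:, None]).mean(axis=1)
    tss = sens + spec - 1.0
    # smallest maximizer, tolerant of float noise among tied candidates
    best = int(np.argmax(tss >= tss.max() - 1e-9))
    thr = float(candidates[best])
    s, p = _rates_at(scores, labels, thr)
    correct = float(((scores >= thr) == (labels == 1)).mean())
    report = ValidationReport(
        auc=auc(scores, labels), threshold=thr, sensitivity=s, specificity=p,
        tss=s + p - 1.0, correct_classification=correct,
        misclassification=1.0 - correct, tag=tag)
    return thr, report


def binarize(prob_map: RasterGrid, threshold: float) -> RasterGrid:
    """Cell = 1 iff probability >= threshold; nodata propagates."""
    if not 0 <= threshold <= 1:
        raise GridValidationError("threshold must lie in [0, 1]")
    out = np.where(prob_map.valid, (prob_map.values >= threshold).astype(np.int8), 0)
    return prob_map.like(out.astype(np.int8))
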