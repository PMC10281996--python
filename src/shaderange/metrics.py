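"""Discrimination metrics for presence/absence scores: AUC, TSS, and the
sensitivity+specificity-maximizing binarization threshold.

AUC follows the Mann–Whitney formulation (probability that a random presence
outranks a random absence, ties counted 1/2). TSS = sensitivity +
specificity - 1 at a threshold; the binarization threshold for mapping is
the one maximizing sensitivity + specificity ("max SSS"), with predictions
positive when score >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def auc(scores, labels) -> float:
    """Rank-based AUC (Mann–Whitney with ties at 0.5)."""
    scores, labels = _validate(scores, labels)
    return float(roc_auc_score(labels, scores))


def tss_at(scores, labels, threshold: float) -> ThresholdMetrics:
    """Confusion-matrix metrics at a threshold (positive iff score >= t)."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    sens = float(pred[pos].mean())
    spec = float((~pred[~pos]).mean())
    return ThresholdMetrics(threshold=float(threshold),
                            sensitivity=sens, specificity=spec)


def optimize_threshold(scores, labels) -> ThresholdMetrics:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the midpoints between adjacent distinct scores plus the
    half-open end intervals. When a run of adjacent candidate intervals ties
    at the maximum, the midpoint of the whole maximizing score interval is
    returned (stable under score jitter). The reported threshold is clipped
    into (0, 1).
    """
    scores, labels = _validate(scores, labels)
    u = np.unique(scores)
    # interval edges: below the minimum, between scores, above the maximum
    edges = np.concatenate([[min(0.0, u[0]) - 1e-9], u, [max(1.0, u[-1]) + 1e-9]])
    candidates = (edges[:-1] + edges[1:]) / 2.0
    sums = np.array([tss_at(scores, labels, t).tss for t in candidates])
    best = sums.max()
    hits = np.flatnonzero(np.isclose(sums, best))
    # first maximal run of consecutive tied intervals
    run_end = hits[0]
    while run_end + 1 in hits:
        run_end += 1
    left = edges[hits[0]]
    right = edges[run_end + 1]
    threshold = float(np.clip((left + right) / 2.0, 1e-9, 1.0 - 1e-9))
    return tss_at(scores, labels, threshold)
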