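"""Crowd aggregation baselines, threshold binarization, and confusion matrices.

Binarization is strict: a probabilistic diagnosis counts as positive only
when it lies strictly above the discrimination threshold, so a boundary
probability is a negative call.  Majority voting likewise requires a strict
majority of positive reader calls; an even-panel tie is a negative
diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import CaseSet, DiagnosisSet, ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class Classifier:
    """A diagnosis source paired with its discrimination threshold."""

    source_id: str
    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError(f"threshold {self.threshold} must lie in (0, 1)")


def binarize(diag: DiagnosisSet, t: float) -> dict[str, int]:
    """Binary predictions: 1 iff probability strictly exceeds ``t``."""
    if not 0.0 < t < 1.0:
        raise ValidationError(f"threshold {t} must lie in (0, 1)")
    return {cid: int(p > t) for cid, p in diag.probabilities.items()}


def _check_same_coverage(sets: Sequence[DiagnosisSet]) -> tuple[str, ...]:
    if not sets:
        raise ValidationError("need at least one diagnosis set")
    cases = set(sets[0].probabilities)
    for s in sets[1:]:
        if set(s.probabilities) != cases:
            raise ValidationError(
                f"source {s.source_id!r} covers different cases than "
                f"{sets[0].source_id!r}"
            )
    return sets[0].case_ids


def crowd_mean(sets: Sequence[DiagnosisSet], source_id: str = "crowd_mean") -> DiagnosisSet:
    """Per-case arithmetic mean of reader probabilities."""
    ids = _check_same_coverage(sets)
    probs = {cid: float(np.mean([s.probabilities[cid] for s in sets])) for cid in ids}
    return DiagnosisSet(source_id, "crowd_mean", probs)


def crowd_majority(
    sets: Sequence[DiagnosisSet], cutoff: float = 0.5, source_id: str = "crowd_majority"
) -> DiagnosisSet:
    """Strict-majority vote of binarized reader calls; ties are negative."""
    ids = _check_same_coverage(sets)
    votes = [binarize(s, cutoff) for s in sets]
    probs = {
        cid: float(sum(v[cid] for v in votes) > len(sets) / 2.0) for cid in ids
    }
    return DiagnosisSet(source_id, "crowd_majority", probs)


def confusion(predictions: Mapping[str, int], cases: CaseSet) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix of binary predictions against labels."""
    tp = fp = tn = fn = 0
    for cid, label in zip(cases.case_ids, cases.labels):
        if cid not in predictions:
            raise ValidationError(f"missing prediction for case {cid!r}")
        pred = predictions[cid]
        if pred not in (0, 1):
            raise ValidationError(f"non-binary prediction {pred!r} for case {cid!r}")
        if label == 1:
            tp, fn = (tp + 1, fn) if pred == 1 else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred == 1 else (fp, tn + 1)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def confusion_from_rates(sens: float, spec: float, n_pos: int, n_neg: int) -> ConfusionMatrix:
    """Invert printed sensitivity/specificity into integer counts.

    Printed rates are themselves rounded, so counts are recovered by
    nearest-integer (half-up) inversion: TP = round(sens * n_pos),
    TN = round(spec * n_neg), with FN/FP as complements.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValidationError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValidationError("class counts must be positive")
    tp = _round_half_up(sens * n_pos)
    tn = _round_half_up(spec * n_neg)
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


def youden_threshold(diag: DiagnosisSet, cases: CaseSet) -> float:
    """Observed-probability threshold maximizing Youden's J = sens + spec - 1.

    Candidates are the observed probabilities themselves; under the strict
    ``> t`` rule each candidate produces a distinct operating point.  Ties
    resolve to the smallest threshold.
    """
    probs = diag.aligned(cases)
    labels = cases.label_array()
    if cases.n_pos == 0 or cases.n_neg == 0:
        raise ValidationError("Youden threshold needs both classes present")
    best_t, best_j = None, -np.inf
    for t in sorted(set(float(p) for p in probs)):
        pred = probs > t
        sens = float(np.mean(pred[labels == 1]))
        spec = float(np.mean(~pred[labels == 0]))
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_t, best_j = t, j
    return float(best_t)
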