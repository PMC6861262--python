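"""Diagnostic performance metrics with percentile-bootstrap inference.

Five performance metrics (percent correct, mean absolute error, Brier
score, AUC, F1) plus sensitivity and specificity.  Confidence intervals
come from a percentile bootstrap over case-level resamples with
replacement (unstratified by default; resample size equals the original
size).  Resamples on which a metric is undefined — single-class draws for
AUC, sensitivity or specificity — are redrawn and the redraw count logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

from .classify_aggregate import ConfusionMatrix, binarize, confusion
from .core_io import CaseSet, DiagnosisSet, ValidationError

log = logging.getLogger("swarmdx")

METRIC_NAMES = ("percent_correct", "mae", "brier", "auc", "f1", "sensitivity", "specificity")

# metrics whose value depends only on the binarized predictions
_THRESHOLDED = {"percent_correct", "f1", "sensitivity", "specificity"}
# metrics undefined when a resample draws a single class
_NEEDS_BOTH_CLASSES = {"auc", "sensitivity", "specificity"}


@dataclass(frozen=True)
class MetricReport:
    source_id: str
    metric: str
    value: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    n_boot: int
    seed: int | None
    n_redraws: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------- cm metrics

def percent_correct(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def f1(cm: ConfusionMatrix) -> float:
    if cm.tp + cm.fp + cm.fn == 0:
        raise ValidationError("F1 undefined on an all-zero matrix")
    if cm.tp == 0:
        warnings.warn("F1 is 0: no true positives", stacklevel=2)
        return 0.0
    return 2.0 * cm.tp / (2.0 * cm.tp + cm.fp + cm.fn)


def sensitivity(cm: ConfusionMatrix) -> float:
    if cm.n_pos == 0:
        raise ValidationError("sensitivity undefined without positive cases")
    return cm.tp / cm.n_pos


def specificity(cm: ConfusionMatrix) -> float:
    if cm.n_neg == 0:
        raise ValidationError("specificity undefined without negative cases")
    return cm.tn / cm.n_neg


# ------------------------------------------------------------ series metrics

def mae(diag: DiagnosisSet, cases: CaseSet) -> float:
    """Mean absolute error of probabilities against binary labels."""
    p = diag.aligned(cases)
    y = cases.label_array()
    return float(np.mean(np.abs(p - y)))


def brier(diag: DiagnosisSet, cases: CaseSet) -> float:
    """Mean squared error of probabilities against binary labels."""
    p = diag.aligned(cases)
    y = cases.label_array()
    return float(np.mean((p - y) ** 2))


def auc(diag: DiagnosisSet, cases: CaseSet) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half.

    Refused for augmented sets: their probabilities mix the machine scale
    (centred near its low threshold) with the human scale (centred near
    50%), so the ranking is not meaningful across the two provenances.
    """
    if diag.kind == "augmented" or diag.provenance is not None:
        raise ValidationError(
            f"AUC not applicable to mixed-scale source {diag.source_id!r}"
        )
    p = diag.aligned(cases)
    y = cases.label_array()
    if cases.n_pos == 0 or cases.n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(y, p))


def _metric_value(name: str, p: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """Array-level metric kernel shared by point estimates and the bootstrap."""
    if name == "mae":
        return float(np.mean(np.abs(p - y)))
    if name == "brier":
        return float(np.mean((p - y) ** 2))
    if name == "auc":
        return float(roc_auc_score(y, p))
    pred = p > threshold
    pos = y == 1
    if name == "percent_correct":
        return 100.0 * float(np.mean(pred == pos))
    if name == "sensitivity":
        return float(np.mean(pred[pos]))
    if name == "specificity":
        return float(np.mean(~pred[~pos]))
    if name == "f1":
        tp = int(np.sum(pred & pos))
        denom = 2 * tp + int(np.sum(pred & ~pos)) + int(np.sum(~pred & pos))
        return 0.0 if denom == 0 else 2.0 * tp / denom
    raise ValidationError(f"unknown metric {name!r}")


def evaluate(name: str, diag: DiagnosisSet, cases: CaseSet, threshold: float = 0.5) -> float:
    """Point value of a named metric for one source."""
    if name not in METRIC_NAMES:
        raise ValidationError(f"unknown metric {name!r}; expected one of {METRIC_NAMES}")
    if name == "auc":
        return auc(diag, cases)
    if name in _THRESHOLDED:
        cm = confusion(binarize(diag, threshold), cases)
        return {"percent_correct": percent_correct, "f1": f1,
                "sensitivity": sensitivity, "specificity": specificity}[name](cm)
    return {"mae": mae, "brier": brier}[name](diag, cases)


def individual_average(
    readers,
    cases: CaseSet,
    name: str,
    threshold: float = 0.5,
    variant: str = "pooled",
) -> float:
    """Average individual-reader performance across a panel.

    Two conventions exist when group sizes differ and neither is canonical:
    ``pooled`` concatenates every reader's diagnoses into one set (each case
    replicated per reader) and scores that, weighting readers by their case
    count; ``group_mean`` scores each reader separately and averages the
    per-reader values, weighting readers equally.
    """
    readers = list(readers)
    if not readers:
        raise ValidationError("need at least one reader")
    if variant == "group_mean":
        return float(np.mean([evaluate(name, r, cases, threshold) for r in readers]))
    if variant != "pooled":
        raise ValidationError(f"unknown variant {variant!r}")
    ids, labels, probs = [], [], {}
    for r in readers:
        r.check_covers(cases)
        for cid, lab in zip(cases.case_ids, cases.labels):
            pid = f"{r.source_id}:{cid}"
            ids.append(pid)
            labels.append(lab)
            probs[pid] = r.probabilities[cid]
    pooled_cases = CaseSet(tuple(ids), tuple(labels))
    pooled = DiagnosisSet("individual_pooled", "reader", probs)
    return evaluate(name, pooled, pooled_cases, threshold)


# ------------------------------------------------------------------ bootstrap

def bootstrap_ci(
    name: str,
    diag: DiagnosisSet,
    cases: CaseSet,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    threshold: float = 0.5,
    stratified: bool = False,
) -> MetricReport:
    """Percentile bootstrap CI for a named metric over case resamples.

    ``stratified=True`` resamples within each label class separately,
    preserving the class balance of every resample.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValidationError("CI level must lie in (0, 1)")
    point = evaluate(name, diag, cases, threshold)  # raises if undefined
    p = diag.aligned(cases)
    y = cases.label_array()
    n = len(y)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)

    values = np.empty(n_boot)
    n_redraws = 0
    for b in range(n_boot):
        while True:
            if stratified:
                idx = np.concatenate([
                    rng.choice(pos_idx, size=len(pos_idx), replace=True),
                    rng.choice(neg_idx, size=len(neg_idx), replace=True),
                ])
            else:
                idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if name in _NEEDS_BOTH_CLASSES and (yb.sum() == 0 or yb.sum() == n):
                n_redraws += 1
                continue
            break
        values[b] = _metric_value(name, p[idx], yb, threshold)
    if n_redraws:
        log.info("bootstrap %s/%s: %d single-class resamples redrawn",
                 diag.source_id, name, n_redraws)
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return MetricReport(
        source_id=diag.source_id, metric=name, value=point,
        ci_lower=float(lo), ci_upper=float(hi), ci_level=level,
        n_boot=n_boot, seed=seed, n_redraws=n_redraws,
    )


def paired_bootstrap_pvalue(
    diag_a: DiagnosisSet,
    diag_b: DiagnosisSet,
    name: str,
    cases: CaseSet,
    n_boot: int = 10_000,
    seed: int | None = None,
    threshold_a: float = 0.5,
    threshold_b: float = 0.5,
) -> float:
    """Two-sided paired-bootstrap p-value for a metric difference.

    Both sources are evaluated on the same case resamples; the p-value is
    twice the fraction of resamples on which the metric difference loses
    the sign of the observed difference, capped at 1.  Identical sources
    give p = 1 by convention.
    """
    pa = diag_a.aligned(cases)
    pb = diag_b.aligned(cases)
    y = cases.label_array()
    n = len(y)
    d_obs = (_metric_value(name, pa, y, threshold_a)
             - _metric_value(name, pb, y, threshold_b))
    if d_obs == 0.0:
        return 1.0
    rng = np.random.default_rng(seed)
    sign = 1.0 if d_obs > 0 else -1.0
    flips = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if name in _NEEDS_BOTH_CLASSES and (yb.sum() == 0 or yb.sum() == n):
            continue
        d = (_metric_value(name, pa[idx], yb, threshold_a)
             - _metric_value(name, pb[idx], yb, threshold_b))
        if sign * d <= 0.0:
            flips += 1
        done += 1
    return min(1.0, 2.0 * flips / n_boot)
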