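"""Human-in-the-loop augmentation: confidence-band deferral to the swarm.

A machine classifier with a low discrimination threshold is confident far
from that threshold and unreliable near it.  The augmentation model routes
every case whose machine probability falls inside a closed low-confidence
band around the threshold (default [0.025, 0.055] around 0.04008) to the
human swarm, whose diagnosis replaces the machine's.  Routed cases are
binarized at the human 50% threshold downstream; all other cases keep the
machine diagnosis and its own threshold.

The sensitivity sweep generalizes the band: cases are ranked by distance to
the machine threshold and routed in matched positive/negative-predicted
pairs, from 0 cases (machine alone) to all cases (swarm alone), with a
percentile-bootstrap confidence band on accuracy at every grid point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.special import logit

from .classify_aggregate import binarize
from .core_io import CaseSet, DiagnosisSet, ValidationError

log = logging.getLogger("swarmdx")


@dataclass(frozen=True)
class AugmentationPlan:
    """Which cases are deferred to the swarm, split by machine-predicted sign."""

    band: tuple[float, float]
    ml_source: str
    routed_positive: tuple[str, ...]  # machine-predicted positive (p > threshold)
    routed_negative: tuple[str, ...]

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise ValidationError(f"band lower bound {lo} must be < upper {hi}")

    @property
    def routed(self) -> tuple[str, ...]:
        return self.routed_negative + self.routed_positive

    def __len__(self) -> int:
        return len(self.routed_positive) + len(self.routed_negative)


@dataclass
class SweepPoint:
    k: int
    fraction: float
    routed: tuple[str, ...]
    accuracy: float
    ci_lower: float
    ci_upper: float
    delta_vs_ml: float
    asymmetric: bool = False


@dataclass
class SweepResult:
    """Deferral-fraction grid with bootstrap accuracy bands."""

    points: list[SweepPoint]
    level: float
    n_boot: int
    seed: int | None
    ml_accuracy: float
    swarm_accuracy: float

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "ml_accuracy": self.ml_accuracy,
            "swarm_accuracy": self.swarm_accuracy,
            "points": [
                {k: v for k, v in asdict(p).items() if k != "routed"}
                for p in self.points
            ],
        }


def route(
    ml: DiagnosisSet,
    band: tuple[float, float],
    threshold: float = 0.04008,
) -> AugmentationPlan:
    """Select the low-confidence cases: machine probability in the closed band."""
    if len(ml) == 0:
        raise ValidationError("cannot route from an empty diagnosis set")
    lo, hi = band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError(f"band {band} must satisfy 0 <= lo < hi <= 1")
    pos, neg = [], []
    for cid, p in ml.probabilities.items():
        if lo <= p <= hi:
            (pos if p > threshold else neg).append(cid)
    log.info("routing band [%g, %g]: %d cases (%d pos-pred, %d neg-pred)",
             lo, hi, len(pos) + len(neg), len(pos), len(neg))
    return AugmentationPlan(band=(lo, hi), ml_source=ml.source_id,
                            routed_positive=tuple(pos), routed_negative=tuple(neg))


def augment(ml: DiagnosisSet, swarm: DiagnosisSet, plan: AugmentationPlan) -> DiagnosisSet:
    """Substitute swarm probabilities on routed cases; machine elsewhere.

    The result records per-case provenance, so mixed-scale metrics (AUC)
    are refused downstream.
    """
    routed = set(plan.routed)
    missing = [c for c in routed if c not in swarm.probabilities]
    if missing:
        raise ValidationError(f"swarm missing routed cases {sorted(missing)[:5]}")
    probs, prov = {}, {}
    for cid, p in ml.probabilities.items():
        if cid in routed:
            probs[cid] = swarm.probabilities[cid]
            prov[cid] = swarm.source_id
        else:
            probs[cid] = p
            prov[cid] = ml.source_id
    return DiagnosisSet(f"augmented_{ml.source_id}+{swarm.source_id}", "augmented",
                        probs, provenance=prov)


def augment_predictions(
    ml: DiagnosisSet,
    swarm: DiagnosisSet,
    plan: AugmentationPlan,
    t_ml: float = 0.04008,
    t_human: float = 0.5,
) -> DiagnosisSet:
    """Final binary calls of the augmented model, as a {0,1}-valued set.

    Routed cases are binarized at the human threshold, the rest at the
    machine threshold, resolving the two probability scales into one
    prediction set that any thresholded metric can consume (at cutoff 0.5).
    """
    aug = augment(ml, swarm, plan)
    routed = set(plan.routed)
    preds = {}
    for cid, p in aug.probabilities.items():
        t = t_human if cid in routed else t_ml
        preds[cid] = float(p > t)
    return DiagnosisSet(aug.source_id + "_binary", "augmented", preds,
                        provenance=dict(aug.provenance))


def _ranked_sides(
    ml: DiagnosisSet, t: float, distance: str
) -> tuple[list[str], list[str]]:
    """Case ids split by machine-predicted sign, each sorted by closeness to t."""
    if distance == "prob":
        dist = {c: abs(p - t) for c, p in ml.probabilities.items()}
    elif distance == "logit":
        eps = 1e-12
        lt = logit(t)
        dist = {c: abs(logit(min(max(p, eps), 1 - eps)) - lt)
                for c, p in ml.probabilities.items()}
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    pos = sorted((c for c, p in ml.probabilities.items() if p > t), key=lambda c: (dist[c], c))
    neg = sorted((c for c, p in ml.probabilities.items() if p <= t), key=lambda c: (dist[c], c))
    return pos, neg


def sweep(
    ml: DiagnosisSet,
    swarm: DiagnosisSet,
    cases: CaseSet,
    t: float = 0.04008,
    grid: Sequence[int] | None = None,
    n_boot: int = 1000,
    level: float = 0.90,
    seed: int | None = None,
    t_human: float = 0.5,
    distance: str = "prob",
    balance: str = "prediction",
) -> SweepResult:
    """Deferral-fraction sensitivity analysis.

    At grid point ``k`` (an even total count of routed cases), the ``k/2``
    machine-predicted-positive and ``k/2`` machine-predicted-negative cases
    closest to the machine threshold are deferred to the swarm; when one
    side runs out, the remainder comes from the other side (flagged
    asymmetric).  ``balance='label'`` balances by ground truth instead of
    predicted sign.  Accuracy at each point carries a percentile-bootstrap
    CI over case resamples; the endpoints reproduce the machine-only and
    swarm-only accuracies exactly.
    """
    ml.check_covers(cases)
    swarm.check_covers(cases)
    n = len(cases)
    if grid is None:
        grid = list(range(0, n + 1, 2))
        if grid[-1] != n:
            grid.append(n)
    if balance == "prediction":
        pos, neg = _ranked_sides(ml, t, distance)
    elif balance == "label":
        lm = cases.label_map
        allpos, allneg = _ranked_sides(ml, t, distance)
        ranked = sorted(allpos + allneg,
                        key=lambda c: (abs(ml.probabilities[c] - t), c))
        pos = [c for c in ranked if lm[c] == 1]
        neg = [c for c in ranked if lm[c] == 0]
    else:
        raise ValidationError(f"unknown balance {balance!r}")

    labels = cases.label_array()
    ml_pred = binarize(ml, t)
    sw_pred = binarize(swarm, t_human)
    ml_correct = np.array([ml_pred[c] == l for c, l in zip(cases.case_ids, cases.labels)])
    sw_correct = np.array([sw_pred[c] == l for c, l in zip(cases.case_ids, cases.labels)])
    idx_of = {c: i for i, c in enumerate(cases.case_ids)}
    ml_acc = 100.0 * float(ml_correct.mean())
    sw_acc = 100.0 * float(sw_correct.mean())

    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    points = []
    for k in grid:
        if not 0 <= k <= n:
            raise ValidationError(f"grid point {k} outside [0, {n}]")
        take_pos = min((k + 1) // 2, len(pos))  # odd k rounds the positive side up
        take_neg = min(k - take_pos, len(neg))
        take_pos = min(k - take_neg, len(pos))  # spill if one side is exhausted
        asymmetric = take_pos != take_neg and k < n
        routed = tuple(neg[:take_neg]) + tuple(pos[:take_pos])
        correct = ml_correct.copy()
        for c in routed:
            correct[idx_of[c]] = sw_correct[idx_of[c]]
        acc = 100.0 * float(correct.mean())
        boot_acc = 100.0 * correct[boot_idx].mean(axis=1)
        alpha = 1.0 - level
        lo, hi = np.quantile(boot_acc, [alpha / 2.0, 1.0 - alpha / 2.0])
        points.append(SweepPoint(
            k=take_pos + take_neg, fraction=(take_pos + take_neg) / n, routed=routed,
            accuracy=acc, ci_lower=float(lo), ci_upper=float(hi),
            delta_vs_ml=acc - ml_acc, asymmetric=asymmetric,
        ))
    return SweepResult(points=points, level=level, n_boot=n_boot, seed=seed,
                       ml_accuracy=ml_acc, swarm_accuracy=sw_acc)
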