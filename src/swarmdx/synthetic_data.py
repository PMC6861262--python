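"""Synthetic study generator with analytically calibrated operating points.

No case-level data from the original reader study is public, so every
pipeline stage is exercised on synthetic data built from a class-conditional
logit-normal model: for a source with target sensitivity ``sens`` and
specificity ``spec`` at threshold ``t``, per-case probabilities are drawn as

    logit(p) ~ Normal(mu_class, sigma)
    mu_pos = logit(t) + sigma * Phi^-1(sens)
    mu_neg = logit(t) - sigma * Phi^-1(spec)

so that P(p > t | positive) = sens and P(p <= t | negative) = spec hold
exactly in expectation, at any threshold.  The machine source uses a small
sigma to compress its probabilities near its low threshold, reproducing the
scale mismatch between machine (centred near 4%) and human (centred near
50%) diagnoses that motivates the deferral band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, ndtri

from .core_io import CaseSet, DiagnosisSet, ValidationError

log = logging.getLogger("swarmdx")


@dataclass(frozen=True)
class OperatingPoint:
    """Target (sensitivity, specificity) at a threshold, with logit-scale spread."""

    sensitivity: float
    specificity: float
    threshold: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} {v} must lie in (0, 1)")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValidationError(f"sigma {self.sigma} must be positive and finite")

    @property
    def mu_pos(self) -> float:
        return float(logit(self.threshold) + self.sigma * ndtri(self.sensitivity))

    @property
    def mu_neg(self) -> float:
        return float(logit(self.threshold) - self.sigma * ndtri(self.specificity))

    def expected_accuracy_at(self, prevalence: float) -> float:
        """Closed-form accuracy fraction: prevalence-weighted sens/spec."""
        return prevalence * self.sensitivity + (1.0 - prevalence) * self.specificity


@dataclass(frozen=True)
class ScenarioPreset:
    """Study conditions for the 50-case two-group reader scenario.

    Defaults: 50 cases with 20 positive / 30 negative (prevalence 0.4);
    reader groups of 7 and 6; readers operating near sensitivity 0.65 /
    specificity 0.85 at the 50% cutoff with moderate between-reader
    variation; a machine model at sensitivity 0.90 / specificity 0.767 at
    its 4.008% threshold with compressed probabilities (sigma 0.8).

    ``case_difficulty_sd`` is the logit-scale spread of a per-case random
    effect shared by every reader (the machine is unaffected): some cases
    look hard to the whole panel.  Reader locations are calibrated against
    the total spread, so each individual's marginal operating point still
    hits the target exactly, while consensus aggregates (crowd mean, swarm)
    can only average away the idiosyncratic part.  With the defaults
    (sigma 1, sd 1) the infinite-panel consensus operating point is
    sensitivity ~0.71 / specificity ~0.93 — the observed gap between
    individual readers and a 13-reader consensus.  Setting it to 0 makes
    reader errors independent.
    """

    n_cases: int = 50
    prevalence: float = 0.4
    group_sizes: tuple[int, ...] = (7, 6)
    reader_op: OperatingPoint = field(
        default_factory=lambda: OperatingPoint(0.65, 0.85, 0.5, sigma=1.0)
    )
    between_reader_sd: float = 0.25
    case_difficulty_sd: float = 1.0
    ml_op: OperatingPoint = field(
        default_factory=lambda: OperatingPoint(0.90, 0.767, 0.04008, sigma=0.8)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError("prevalence must lie in (0, 1)")
        if any(g < 2 for g in self.group_sizes):
            raise ValidationError("every reader group needs at least 2 readers")
        if self.between_reader_sd < 0:
            raise ValidationError("between_reader_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioBundle:
    cases: CaseSet
    groups: dict[str, list[DiagnosisSet]]
    ml: DiagnosisSet
    preset: ScenarioPreset


def gen_cases(n: int, prevalence: float, seed: int | None = None) -> CaseSet:
    """Cases with a deterministic class composition; only ordering is random.

    The positive count is round(n * prevalence) (half-up), so (50, 0.4)
    always yields exactly 20 positives and 30 negatives.
    """
    if n < 2:
        raise ValidationError("need at least 2 cases")
    n_pos = int(math.floor(n * prevalence + 0.5))
    if n_pos == 0 or n_pos == n:
        raise ValidationError(
            f"prevalence {prevalence} with n={n} leaves a class empty"
        )
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    width = len(str(n))
    ids = tuple(f"case_{i + 1:0{width}d}" for i in range(n))
    return CaseSet(ids, tuple(int(l) for l in labels))


def gen_probs(
    cases: CaseSet,
    op: OperatingPoint,
    seed: int | None = None,
    source_id: str = "synthetic",
    kind: str = "reader",
    mu_shift: float = 0.0,
    case_effects: np.ndarray | None = None,
    case_effect_sd: float = 0.0,
) -> DiagnosisSet:
    """Class-conditional logit-normal probabilities calibrated to ``op``.

    ``mu_shift`` translates both class locations on the logit scale and is
    used for reader-to-reader variation.  ``case_effects`` (one logit-scale
    offset per case, drawn with spread ``case_effect_sd``) models shared
    case difficulty; class locations are then calibrated against the total
    spread sqrt(sigma^2 + case_effect_sd^2), so the marginal operating
    point still matches ``op`` exactly.
    """
    rng = np.random.default_rng(seed)
    y = cases.label_array()
    if case_effects is None:
        mu = np.where(y == 1, op.mu_pos, op.mu_neg) + mu_shift
    else:
        if len(case_effects) != len(cases):
            raise ValidationError("need one case effect per case")
        total = math.hypot(op.sigma, case_effect_sd)
        lt = float(logit(op.threshold))
        mu_pos = lt + total * float(ndtri(op.sensitivity))
        mu_neg = lt - total * float(ndtri(op.specificity))
        mu = np.where(y == 1, mu_pos, mu_neg) + mu_shift + np.asarray(case_effects)
    z = rng.normal(mu, op.sigma)
    p = expit(z)
    # expit is (0, 1)-valued but float rounding can reach the endpoints
    p = np.clip(p, 1e-15, 1.0 - 1e-15)
    probs = {cid: float(v) for cid, v in zip(cases.case_ids, p)}
    return DiagnosisSet(source_id, kind, probs)


def gen_reader_panel(
    cases: CaseSet,
    n_readers: int,
    op: OperatingPoint,
    between_reader_sd: float = 0.25,
    seed: int | None = None,
    prefix: str = "reader",
    case_effects: np.ndarray | None = None,
    case_effect_sd: float = 0.0,
) -> list[DiagnosisSet]:
    """A panel of exchangeable readers with jittered operating points.

    Each reader's class locations are shifted by an i.i.d. normal draw with
    the given logit-scale spread; ``between_reader_sd = 0`` collapses the
    panel onto a single shared operating point.  ``case_effects`` is a
    panel-wide difficulty offset per case (see :func:`gen_probs`).
    """
    if n_readers < 2:
        raise ValidationError("a panel needs at least 2 readers")
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed if seed is not None else 0)
    shift_rng = np.random.default_rng(ss.spawn(1)[0])
    shifts = shift_rng.normal(0.0, between_reader_sd, size=n_readers)
    children = ss.spawn(n_readers + 1)[1:]
    return [
        gen_probs(cases, op, seed=child, source_id=f"{prefix}_{i + 1}",
                  kind="reader", mu_shift=float(shifts[i]),
                  case_effects=case_effects, case_effect_sd=case_effect_sd)
        for i, child in enumerate(children)
    ]


def pilot_study_scenario(
    seed: int | None = None, preset: ScenarioPreset | None = None
) -> ScenarioBundle:
    """The full two-group study bundle under the default scenario conditions."""
    preset = preset or ScenarioPreset()
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    case_seed, ml_seed, effect_seed, *group_seeds = ss.spawn(3 + len(preset.group_sizes))
    cases = gen_cases(preset.n_cases, preset.prevalence, seed=case_seed)
    effects = np.random.default_rng(effect_seed).normal(
        0.0, preset.case_difficulty_sd, size=len(cases)
    )
    groups: dict[str, list[DiagnosisSet]] = {}
    for gi, (size, gseed) in enumerate(zip(preset.group_sizes, group_seeds)):
        gname = chr(ord("A") + gi)
        groups[gname] = gen_reader_panel(
            cases, size, preset.reader_op, preset.between_reader_sd,
            seed=gseed, prefix=f"reader_{gname}",
            case_effects=effects, case_effect_sd=preset.case_difficulty_sd,
        )
    ml = gen_probs(cases, preset.ml_op, seed=ml_seed, source_id="chexmax_like", kind="ml")
    log.info("generated scenario: %d cases, groups %s, ml source",
             len(cases), {g: len(r) for g, r in groups.items()})
    return ScenarioBundle(cases=cases, groups=groups, ml=ml, preset=preset)
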