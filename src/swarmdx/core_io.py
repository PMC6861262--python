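"""Domain types, CSV/JSON I/O, study configuration, and pipeline orchestration.

A study revolves around two containers: a :class:`CaseSet` holding the
binary ground-truth label of every case (1 = pneumonia, 0 = no pneumonia),
and one :class:`DiagnosisSet` per diagnostic source (an individual reader,
a crowd aggregate, a simulated swarm, or a machine model) mapping each case
to a probability of disease in [0, 1].  Probabilities are always stored as
decimals, never percent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("swarmdx")

KINDS = ("reader", "crowd_mean", "crowd_majority", "swarm", "ml", "augmented")


class ValidationError(ValueError):
    """Raised when an input table or container violates the data contract."""


@dataclass(frozen=True)
class CaseSet:
    """Ground-truth labels for a diagnostic case collection.

    Labels are strictly binary with 1 the positive (disease) class.  Case
    identifiers are opaque, unique, non-empty strings; insertion order is
    preserved and meaningful for reproducibility.
    """

    case_ids: tuple[str, ...]
    labels: tuple[int, ...]
    metadata: Mapping[str, Mapping[str, str]] | None = None

    def __post_init__(self) -> None:
        if len(self.case_ids) != len(self.labels):
            raise ValidationError("case_ids and labels differ in length")
        if any(not isinstance(c, str) or not c for c in self.case_ids):
            raise ValidationError("case ids must be non-empty strings")
        if len(set(self.case_ids)) != len(self.case_ids):
            dupes = sorted({c for c in self.case_ids if self.case_ids.count(c) > 1})
            raise ValidationError(f"duplicate case ids: {dupes}")
        if any(l not in (0, 1) for l in self.labels):
            raise ValidationError("labels must be strictly binary (0/1)")

    def __len__(self) -> int:
        return len(self.case_ids)

    @property
    def n_pos(self) -> int:
        return sum(self.labels)

    @property
    def n_neg(self) -> int:
        return len(self.labels) - self.n_pos

    @property
    def label_map(self) -> dict[str, int]:
        return dict(zip(self.case_ids, self.labels))

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    def subset(self, case_ids: Sequence[str]) -> "CaseSet":
        lm = self.label_map
        return CaseSet(tuple(case_ids), tuple(lm[c] for c in case_ids))


@dataclass(frozen=True)
class DiagnosisSet:
    """One source's per-case probability of disease.

    ``provenance`` (case_id -> originating source_id) is populated only for
    augmented sets, whose probabilities mix two scales (machine probabilities
    centred near its low threshold vs. human probabilities centred near 50%);
    rank-based metrics refuse such sets.
    """

    source_id: str
    kind: str
    probabilities: Mapping[str, float]
    provenance: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        for cid, p in self.probabilities.items():
            if not (isinstance(p, (int, float)) and math.isfinite(p)) or not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"probability {p!r} for case {cid!r} in source {self.source_id!r} "
                    "outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.probabilities)

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(self.probabilities)

    def aligned(self, cases: CaseSet) -> np.ndarray:
        """Probabilities as an array in the case order of ``cases``."""
        missing = [c for c in cases.case_ids if c not in self.probabilities]
        if missing:
            raise ValidationError(
                f"source {self.source_id!r} missing probabilities for cases {missing[:5]}"
            )
        return np.array([self.probabilities[c] for c in cases.case_ids], dtype=float)

    def check_covers(self, cases: CaseSet) -> None:
        self.aligned(cases)


def _validate_prob_cell(value, row: int, column: str) -> float:
    try:
        p = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric probability {value!r} at row {row}, column {column!r}")
    if not math.isfinite(p) or not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability {p} outside [0, 1] at row {row}, column {column!r}")
    return p


def read_case_table(
    path: str | Path, kinds: Mapping[str, str] | None = None
) -> tuple[CaseSet, list[DiagnosisSet]]:
    """Read a case/diagnosis CSV: columns ``case_id, label`` then one per source.

    ``kinds`` optionally maps a source column name to its kind; unlisted
    sources default to ``reader``.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    for required in ("case_id", "label"):
        if required not in df.columns:
            raise ValidationError(f"missing required column {required!r} in {path}")
    labels = []
    for i, v in enumerate(df["label"]):
        if v not in (0, 1):
            raise ValidationError(f"non-binary label {v!r} at row {i}")
        labels.append(int(v))
    cases = CaseSet(tuple(df["case_id"]), tuple(labels))
    kinds = dict(kinds or {})
    sources = []
    for col in df.columns:
        if col in ("case_id", "label"):
            continue
        probs = {
            cid: _validate_prob_cell(v, i, col)
            for i, (cid, v) in enumerate(zip(df["case_id"], df[col]))
        }
        sources.append(DiagnosisSet(col, kinds.get(col, "reader"), probs))
    log.info("read %d cases, %d sources from %s", len(cases), len(sources), path)
    return cases, sources


def write_case_table(cases: CaseSet, sources: Sequence[DiagnosisSet], path: str | Path) -> None:
    """Inverse of :func:`read_case_table`; probabilities written full-precision."""
    data = {"case_id": list(cases.case_ids), "label": list(cases.labels)}
    for s in sources:
        data[s.source_id] = [s.probabilities[c] for c in cases.case_ids]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_report(reports: Sequence[Mapping], path: str | Path) -> None:
    """Write a metric table as JSON (``<path>``) plus a markdown twin (``<path>.md``).

    Each report entry is a flat mapping (typically a serialized MetricReport).
    The JSON form round-trips losslessly; the markdown form is for humans.
    """
    path = Path(path)
    entries = [dict(r) for r in reports]
    path.write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
    cols: list[str] = []
    for e in entries:
        for k in e:
            if k not in cols:
                cols.append(k)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for e in entries:
        lines.append("| " + " | ".join(_fmt(e.get(k, "")) for k in cols) + " |")
    path.with_suffix(path.suffix + ".md").write_text("\n".join(lines) + "\n")
    log.info("wrote report with %d rows to %s", len(entries), path)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def read_report(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


@dataclass
class StudyConfig:
    """Everything a full study run needs: thresholds, band, sweep, bootstrap, seeds.

    Defaults mirror the chest-radiograph pneumonia study design: a 50%
    discrimination threshold for human-scale sources, a low machine threshold
    of 4.008%, a deferral band of [2.5%, 5.5%] around it, 1000-resample
    bootstraps, and a 90% CI for the sweep.
    """

    seed: int = 0
    ml_threshold: float = 0.04008
    human_threshold: float = 0.5
    band: tuple[float, float] = (0.025, 0.055)
    n_boot: int = 1000
    ci_level: float = 0.95
    sweep_enabled: bool = True
    sweep_n_boot: int = 1000
    sweep_level: float = 0.90
    swarm: "object | None" = None  # SwarmConfig; resolved lazily to avoid a cycle
    scenario: "object | None" = None  # ScenarioPreset

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise ValidationError(f"band lower bound {lo} must be < upper bound {hi}")
        if not 0 < self.ci_level < 1 or not 0 < self.sweep_level < 1:
            raise ValidationError("CI level must lie in (0, 1)")
        if self.n_boot < 1 or self.sweep_n_boot < 1:
            raise ValidationError("bootstrap resample count must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = (
            yaml.safe_load(path.read_text())
            if path.suffix in (".yml", ".yaml")
            else json.loads(path.read_text())
        )
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)


def pool_groups(
    cases: CaseSet, per_group: Mapping[str, DiagnosisSet], kind: str, source_id: str
) -> tuple[CaseSet, DiagnosisSet]:
    """Pool one diagnosis set per group over the same cases into a single set.

    Each case is replicated once per group under the id ``<group>:<case_id>``,
    matching the convention that a 50-case set read by two groups yields 100
    pooled diagnoses.
    """
    ids, labels, probs = [], [], {}
    for gname, diag in per_group.items():
        diag.check_covers(cases)
        for cid, lab in zip(cases.case_ids, cases.labels):
            pid = f"{gname}:{cid}"
            ids.append(pid)
            labels.append(lab)
            probs[pid] = diag.probabilities[cid]
    return CaseSet(tuple(ids), tuple(labels)), DiagnosisSet(source_id, kind, probs)


def run_pipeline(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic study: generate → swarm → aggregate → metrics →
    augment → sweep → report.

    Returns a bundle dict; if ``out_dir`` is given, writes the case table,
    per-source metric report JSON/markdown, and sweep JSON there.  All
    randomness descends from ``config.seed``, so identical configs produce
    identical outputs.
    """
    from . import classify_aggregate as ca
    from . import hitl, metrics, swarm_engine, synthetic_data

    preset = config.scenario or synthetic_data.ScenarioPreset()
    swarm_cfg = config.swarm or swarm_engine.SwarmConfig()
    bundle = synthetic_data.pilot_study_scenario(config.seed, preset)
    cases, groups, ml = bundle.cases, bundle.groups, bundle.ml
    log.info("scenario: %d cases (%d+/%d-), groups %s", len(cases), cases.n_pos,
             cases.n_neg, {g: len(r) for g, r in groups.items()})

    ss = np.random.SeedSequence([config.seed, 0x5717])
    group_seeds = {g: int(s.generate_state(1)[0] % 2**31)
                   for g, s in zip(sorted(groups), ss.spawn(len(groups)))}
    swarms = {
        g: swarm_engine.run_swarm_session(
            cases, groups[g],
            config=dataclasses.replace(swarm_cfg, seed=group_seeds[g]),
            source_id=f"swarm_{g}",
        )
        for g in sorted(groups)
    }
    crowd_means = {g: ca.crowd_mean(groups[g], source_id=f"crowd_mean_{g}") for g in groups}
    crowd_majs = {
        g: ca.crowd_majority(groups[g], cutoff=config.human_threshold,
                             source_id=f"crowd_majority_{g}")
        for g in groups
    }

    pooled_cases, pooled_swarm = pool_groups(cases, swarms, "swarm", "swarm_combined")
    _, pooled_ml = pool_groups(cases, {g: ml for g in groups}, "ml", f"{ml.source_id}_pooled")

    # Per-source evaluation at its own discrimination threshold.
    eval_plan = [(ml, cases, config.ml_threshold)]
    for g in sorted(groups):
        eval_plan += [
            (swarms[g], cases, config.human_threshold),
            (crowd_means[g], cases, config.human_threshold),
            (crowd_majs[g], cases, config.human_threshold),
        ]
        eval_plan += [(r, cases, config.human_threshold) for r in groups[g]]
    eval_plan.append((pooled_swarm, pooled_cases, config.human_threshold))

    boot_ss = ss.spawn(1)[0]
    reports = []
    for diag, csel, thr in eval_plan:
        for name in ("percent_correct", "mae", "brier", "auc", "f1", "sensitivity", "specificity"):
            seed = int(boot_ss.generate_state(1)[0] % 2**31)
            boot_ss = boot_ss.spawn(1)[0]
            reports.append(
                metrics.bootstrap_ci(name, diag, csel, n_boot=config.n_boot,
                                     level=config.ci_level, seed=seed, threshold=thr)
            )

    plan = hitl.route(pooled_ml, config.band, threshold=config.ml_threshold)
    augmented = hitl.augment(pooled_ml, pooled_swarm, plan)
    aug_binary = hitl.augment_predictions(
        pooled_ml, pooled_swarm, plan,
        t_ml=config.ml_threshold, t_human=config.human_threshold,
    )
    for name in ("percent_correct", "f1", "sensitivity", "specificity"):
        seed = int(boot_ss.generate_state(1)[0] % 2**31)
        boot_ss = boot_ss.spawn(1)[0]
        reports.append(
            metrics.bootstrap_ci(name, aug_binary, pooled_cases, n_boot=config.n_boot,
                                 level=config.ci_level, seed=seed, threshold=0.5)
        )

    sweep_result = None
    if config.sweep_enabled:
        sweep_seed = int(boot_ss.generate_state(1)[0] % 2**31)
        sweep_result = hitl.sweep(
            pooled_ml, pooled_swarm, pooled_cases, t=config.ml_threshold,
            n_boot=config.sweep_n_boot, level=config.sweep_level, seed=sweep_seed,
            t_human=config.human_threshold,
        )

    bundle_out = {
        "cases": cases,
        "groups": groups,
        "ml": ml,
        "swarms": swarms,
        "crowd_means": crowd_means,
        "crowd_majorities": crowd_majs,
        "pooled_cases": pooled_cases,
        "pooled_swarm": pooled_swarm,
        "augmented": augmented,
        "augmented_binary": aug_binary,
        "plan": plan,
        "reports": reports,
        "sweep": sweep_result,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_sources = [ml] + [r for g in sorted(groups) for r in groups[g]] + [
            swarms[g] for g in sorted(groups)
        ]
        write_case_table(cases, all_sources, out / "case_table.csv")
        write_report([r.to_dict() for r in reports], out / "metrics.json")
        if sweep_result is not None:
            (out / "sweep.json").write_text(json.dumps(sweep_result.to_dict(), indent=2) + "\n")
    return bundle_out


def replicate_accuracies(
    n_replicates: int,
    seed: int = 0,
    preset=None,
    swarm_config=None,
    band: tuple[float, float] = (0.025, 0.055),
    ml_threshold: float = 0.04008,
    human_threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Machine-only, swarm-only and augmented accuracy over seeded replicates.

    Each replicate generates a fresh scenario (replicate seeds descend from
    ``seed``), runs both groups' swarm sessions, pools the diagnoses, and
    applies the confidence-band augmentation.  Returns percent-correct
    arrays keyed ``ml`` / ``swarm`` / ``augmented``, one entry per
    replicate — the end-to-end comparison of the three diagnostic systems.
    """
    import dataclasses as _dc

    from . import hitl, swarm_engine, synthetic_data

    swarm_config = swarm_config or swarm_engine.SwarmConfig()
    rep_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    out = {"ml": np.empty(n_replicates), "swarm": np.empty(n_replicates),
           "augmented": np.empty(n_replicates)}
    for i, rs in enumerate(rep_seeds):
        rep_seed = int(rs.generate_state(1)[0] % 2**31)
        bundle = synthetic_data.pilot_study_scenario(rep_seed, preset)
        gss = np.random.SeedSequence([rep_seed, 0x5717]).spawn(len(bundle.groups))
        swarms = {
            g: swarm_engine.run_swarm_session(
                bundle.cases, bundle.groups[g],
                config=_dc.replace(swarm_config, seed=int(s.generate_state(1)[0] % 2**31)),
                source_id=f"swarm_{g}",
            )
            for g, s in zip(sorted(bundle.groups), gss)
        }
        pooled_cases, pooled_swarm = pool_groups(bundle.cases, swarms, "swarm", "swarm_pooled")
        _, pooled_ml = pool_groups(
            bundle.cases, {g: bundle.ml for g in bundle.groups}, "ml", "ml_pooled"
        )
        plan = hitl.route(pooled_ml, band, threshold=ml_threshold)
        preds = hitl.augment_predictions(pooled_ml, pooled_swarm, plan,
                                         t_ml=ml_threshold, t_human=human_threshold)
        y = pooled_cases.label_array()
        pm = pooled_ml.aligned(pooled_cases)
        ps = pooled_swarm.aligned(pooled_cases)
        pa = preds.aligned(pooled_cases)
        out["ml"][i] = 100.0 * np.mean((pm > ml_threshold) == y)
        out["swarm"][i] = 100.0 * np.mean((ps > human_threshold) == y)
        out["augmented"][i] = 100.0 * np.mean((pa > 0.5) == y)
    return out
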