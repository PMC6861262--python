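"""Headless agent-based simulation of a real-time swarm diagnosis session.

A panel of agents (readers), each holding a private probability of disease,
collectively steers a shared pointer (the "puck") among five answer targets
laid out on the unit circle, one per probability bin.  Each simulation tick
every agent pulls the puck with a unit-magnitude force toward the target of
the bin it currently intends; the puck moves with velocity proportional to
the mean force.  A session ends when the puck dwells inside the convergence
radius of one target, or at the 60 s timeout, in which case the bin with the
largest accumulated impulse wins (ties favour the lower-probability bin).

The behavioural record of a session is the per-bin accumulated impulse
``F(i)`` (force x time directed at bin *i*).  The refined probabilistic
diagnosis is the squared-impulse interpolation

    w_i = F(i)^2 / sum_a F(a)^2,     diagnosis = sum_i w_i * v_i

with ``v_i`` the midpoint of bin *i*.  Two agent policies are provided:
``stubborn`` agents always pull toward their own belief's bin, which makes
the unanimous case exact (all impulse on one bin, diagnosis = midpoint);
``conciliatory`` agents (default) re-sample their intended bin each tick
from a softmax over bins of -|v_bin - belief| / tau, so split panels can
compromise toward adjacent bins and converge.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import CaseSet, DiagnosisSet, ValidationError

log = logging.getLogger("swarmdx")

DEFAULT_EDGES = (0.0, 0.05, 0.25, 0.65, 0.85, 1.0)


@dataclass(frozen=True)
class BinScheme:
    """Contiguous probability bins covering [0, 1], with unit-circle targets.

    Bin *i* spans ``[edges[i], edges[i+1])`` (the last bin is closed above);
    its answer value is the midpoint ``v_i = (lower + upper) / 2``.  Target
    *i* sits on the unit circle at equally spaced angles starting from the
    top, ordered by increasing probability.
    """

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 3:
            raise ValidationError("a bin scheme needs at least two bins")
        if e[0] != 0.0 or e[-1] != 1.0:
            raise ValidationError("bins must cover [0, 1] exactly")
        if any(a >= b for a, b in zip(e, e[1:])):
            raise ValidationError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    def bin_of(self, p: float) -> int:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"probability {p} outside [0, 1]")
        idx = int(np.searchsorted(self.edges, p, side="right")) - 1
        return min(idx, self.n_bins - 1)

    def targets(self) -> np.ndarray:
        """(n_bins, 2) unit-circle target coordinates."""
        angles = np.pi / 2 - 2 * np.pi * np.arange(self.n_bins) / self.n_bins
        return np.column_stack([np.cos(angles), np.sin(angles)])


@dataclass(frozen=True)
class ImpulseProfile:
    """Per-bin accumulated pull F(i), in units of force x seconds."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise ValidationError("impulse values must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class SwarmConfig:
    """Session mechanics: tick 0.1 s, 60 s timeout, pointer kinematics, policy."""

    tick: float = 0.1
    max_duration: float = 60.0
    speed: float = 0.7  # puck units per second at full agreement
    convergence_radius: float = 0.15
    dwell_ticks: int = 5
    policy: str = "conciliatory"
    tau: float = 0.08
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tick <= 0 or self.max_duration < self.tick:
            raise ValidationError("need tick > 0 and timeout >= tick")
        if self.speed <= 0 or self.convergence_radius <= 0 or self.dwell_ticks < 1:
            raise ValidationError("kinematic parameters must be positive")
        if self.policy not in ("stubborn", "conciliatory"):
            raise ValidationError(f"unknown policy {self.policy!r}")
        if self.policy == "conciliatory" and self.tau <= 0:
            raise ValidationError("conciliatory temperature tau must be > 0")


@dataclass
class SwarmTrace:
    """Tick-level record of one session.

    ``puck`` has shape (elapsed_ticks, 2); ``intended`` has shape
    (elapsed_ticks, n_agents) and holds each agent's intended bin per tick.
    Agent force vectors are unit vectors from the puck toward the intended
    target and are reconstructed on demand for JSON export.
    """

    puck: np.ndarray
    intended: np.ndarray
    chosen_bin: int
    converged: bool
    elapsed_ticks: int
    tick: float

    @property
    def elapsed_seconds(self) -> float:
        return self.elapsed_ticks * self.tick

    def agent_forces(self, t: int, scheme: BinScheme) -> np.ndarray:
        targets = scheme.targets()
        d = targets[self.intended[t]] - self.puck[t]
        n = np.linalg.norm(d, axis=1, keepdims=True)
        return np.divide(d, n, out=np.zeros_like(d), where=n > 0)

    def to_json_dict(self, scheme: BinScheme, case_id: str | None = None,
                     profile: "ImpulseProfile | None" = None,
                     interpolated: float | None = None,
                     config: SwarmConfig | None = None) -> dict:
        ticks = []
        for t in range(self.elapsed_ticks):
            forces = self.agent_forces(t, scheme)
            ticks.append({
                "t": round(t * self.tick, 6),
                "puck": [float(x) for x in self.puck[t]],
                "agents": [
                    {"id": a, "force": [float(f[0]), float(f[1])],
                     "intended_bin": int(self.intended[t, a])}
                    for a, f in enumerate(forces)
                ],
            })
        out = {
            "case_id": case_id,
            "config": dataclasses.asdict(config) if config else None,
            "ticks": ticks,
            "chosen_bin": int(self.chosen_bin),
            "converged": bool(self.converged),
        }
        if profile is not None:
            out["impulse"] = list(profile.values)
        if interpolated is not None:
            out["interpolated"] = float(interpolated)
        return out


def _intended_bins(beliefs: np.ndarray, scheme: BinScheme, config: SwarmConfig,
                   n_ticks: int, rng: np.random.Generator) -> np.ndarray:
    """Pre-draw every agent's intended bin for each tick: (n_ticks, n_agents)."""
    own = np.array([scheme.bin_of(float(b)) for b in beliefs])
    if config.policy == "stubborn":
        return np.broadcast_to(own, (n_ticks, len(beliefs))).copy()
    # conciliatory: softmax over bins of -|v_bin - belief| / tau, fixed per
    # agent across the session, so the whole schedule can be drawn up front
    mids = scheme.midpoints
    logits = -np.abs(mids[None, :] - beliefs[:, None]) / config.tau
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random((n_ticks, len(beliefs), 1))
    return (u > np.cumsum(probs, axis=1)[None, :, :]).sum(axis=2)


def simulate_swarm(
    beliefs: Sequence[float],
    scheme: BinScheme | None = None,
    config: SwarmConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SwarmTrace, ImpulseProfile]:
    """Simulate one swarm session for a panel of agent beliefs.

    Returns the tick-level trace and the per-bin accumulated impulse.
    Fully reproducible from ``config.seed`` (or an explicit ``rng``).
    """
    scheme = scheme or BinScheme()
    config = config or SwarmConfig()
    beliefs = np.asarray(list(beliefs), dtype=float)
    if beliefs.size < 2:
        raise ValidationError("a swarm needs at least 2 agents")
    if np.any((beliefs < 0) | (beliefs > 1)):
        raise ValidationError("agent beliefs must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_ticks = int(round(config.max_duration / config.tick))
    intended = _intended_bins(beliefs, scheme, config, n_ticks, rng)
    targets = scheme.targets()

    puck = np.zeros(2)
    puck_hist = np.empty((n_ticks, 2))
    dwell = 0
    dwell_target = -1
    converged = False
    chosen = -1
    elapsed = n_ticks
    step = config.speed * config.tick
    for t in range(n_ticks):
        puck_hist[t] = puck
        d = targets[intended[t]] - puck
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        unit = np.divide(d, norms, out=np.zeros_like(d), where=norms > 0)
        puck = puck + step * unit.mean(axis=0)
        dist = np.linalg.norm(targets - puck, axis=1)
        nearest = int(dist.argmin())
        if dist[nearest] <= config.convergence_radius:
            dwell = dwell + 1 if nearest == dwell_target else 1
            dwell_target = nearest
            if dwell >= config.dwell_ticks:
                converged = True
                chosen = nearest
                elapsed = t + 1
                break
        else:
            dwell = 0
            dwell_target = -1

    counts = np.zeros(scheme.n_bins)
    flat = intended[:elapsed].ravel()
    np.add.at(counts, flat, 1.0)
    impulse = counts * config.tick
    if not converged:
        # timeout: most-supported bin wins; argmax ties resolve to the
        # lowest index, i.e. the lower-probability (negative-leaning) bin
        chosen = int(impulse.argmax())

    trace = SwarmTrace(
        puck=puck_hist[:elapsed].copy(),
        intended=intended[:elapsed].copy(),
        chosen_bin=chosen,
        converged=converged,
        elapsed_ticks=elapsed,
        tick=config.tick,
    )
    return trace, ImpulseProfile(tuple(float(v) for v in impulse))


def interpolate(profile: ImpulseProfile, scheme: BinScheme | None = None) -> float:
    """Squared-impulse interpolation: sum of w_i * v_i with w_i = F(i)^2 / sum F^2."""
    scheme = scheme or BinScheme()
    F = profile.as_array()
    if len(F) != scheme.n_bins:
        raise ValidationError(
            f"profile has {len(F)} bins but scheme has {scheme.n_bins}"
        )
    denom = float(np.sum(F**2))
    if denom <= 0.0:
        raise ValidationError("all-zero impulse profile carries no behavioural signal")
    w = F**2 / denom
    return float(np.sum(w * scheme.midpoints))


def run_swarm_session(
    cases: CaseSet,
    panel: Sequence[DiagnosisSet],
    scheme: BinScheme | None = None,
    config: SwarmConfig | None = None,
    source_id: str = "swarm",
    trace_dir: str | Path | None = None,
) -> DiagnosisSet:
    """Run one swarm session over every case and return interpolated diagnoses.

    Each case gets an independent child seed derived from ``config.seed``.
    If ``trace_dir`` is given, the full per-case trace is written there as
    ``<case_id>.json``.
    """
    scheme = scheme or BinScheme()
    config = config or SwarmConfig()
    if len(panel) < 2:
        raise ValidationError("a swarm session needs at least 2 readers")
    for reader in panel:
        for cid in cases.case_ids:
            if cid not in reader.probabilities:
                raise ValidationError(
                    f"reader {reader.source_id!r} has no probability for case {cid!r}"
                )
    seeds = np.random.SeedSequence(config.seed if config.seed is not None else 0).spawn(
        len(cases)
    )
    probs: dict[str, float] = {}
    for cid, child in zip(cases.case_ids, seeds):
        beliefs = [r.probabilities[cid] for r in panel]
        rng = np.random.default_rng(child)
        trace, profile = simulate_swarm(beliefs, scheme, config, rng=rng)
        value = interpolate(profile, scheme)
        probs[cid] = value
        if trace_dir is not None:
            out = Path(trace_dir)
            out.mkdir(parents=True, exist_ok=True)
            payload = trace.to_json_dict(scheme, case_id=cid, profile=profile,
                                         interpolated=value, config=config)
            (out / f"{cid}.json").write_text(json.dumps(payload) + "\n")
    log.info("swarm session %s: %d cases simulated", source_id, len(cases))
    return DiagnosisSet(source_id, "swarm", probs)
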