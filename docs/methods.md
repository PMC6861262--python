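# Methods

This note documents the models behind `swarmdx`, the defaults and why they
were chosen, and what the synthetic experiments do and do not demonstrate.

## Swarm session model

The simulator emulates a real-time consensus platform in which a panel of
readers steers a shared pointer ("puck") among answer targets. The
commercial platforms that inspired this design do not publish their control
algorithms, so the dynamics here are a deliberately minimal closed-loop
model:

* Five answer bins — (0–5%], (5–25%], (25–65%], (65–85%], (85–100%] — with
  targets at equally spaced angles on the unit circle and answer values at
  the bin midpoints v = (2.5, 15, 45, 75, 92.5)%.
* The puck starts at the origin. Each tick (0.1 s) every agent exerts a
  unit-magnitude force from the puck toward the target of its currently
  intended bin; puck velocity is `speed × mean force` with `speed = 0.7`
  units/s, so a unanimous panel crosses the unit circle in under 2 s.
* A session ends when the puck stays within `convergence_radius = 0.15` of
  one target for 5 consecutive ticks, or at the 60 s timeout. On timeout
  the bin with the largest accumulated impulse wins; exact ties resolve to
  the lower-probability bin, reflecting the specificity-leaning behaviour
  of expert panels on this task.
* **Impulse attribution**: each tick adds `tick × 1` to F(intended bin) of
  each agent — full attribution to the intended bin, not a geometric
  projection onto all bins. This makes the unanimous case exact (all
  impulse on one bin, interpolated diagnosis = that bin's midpoint) and
  lets the interpolation rule be tested in isolation. Whether a real
  platform projects onto all bins instead is unknown; this is a modelling
  choice.
* The real elicitation is a two-step process (coarse bin, then a refined
  value); here the refined value comes directly from the interpolation of
  the impulse profile, collapsing the second step. This is a
  simplification: the interpolation already produces the refined value.

Two agent policies are provided. `stubborn` agents always pull toward their
own belief's bin; this makes unanimity exactly recoverable but deadlocks
split panels. The default `conciliatory` policy re-draws each agent's
intended bin every tick from `softmax(−|v_bin − belief| / τ)` with
temperature τ = 0.08, so agents spend most ticks on their own bin but
compromise toward adjacent bins, which is what lets a split panel converge.
τ = 0.08 puts roughly a 60/40 split between the two nearest bins for a
belief sitting between their midpoints; larger values blur the panel
signal, much smaller ones reduce to the stubborn policy. Because each
agent's bin distribution is constant within a session, the whole intention
schedule is drawn up front, which keeps a 600-tick worst-case session at a
few milliseconds.

### Interpolation

The refined diagnosis is `Σ w_i v_i` with `w_i = F(i)² / Σ_a F(a)²`.
Squaring sharpens the weights toward the dominant bin. Properties enforced
by tests: the value is scale-invariant in F, lies in the convex hull of
midpoints with nonzero impulse, moves (weakly) toward v_i when F(i) grows,
and equals the midpoint exactly when all impulse sits on one bin. An
all-zero profile is an error, not a default value: a completed session
always accumulates impulse.

## Classification and aggregation conventions

* Binarization is strict (`p > t`): a probability exactly at the threshold
  is a negative call. A 3–3 vote in a 6-reader majority is likewise
  negative — a positive diagnosis requires a strict majority.
* The machine discrimination threshold defaults to 4.008% (the value is
  also reported elsewhere as 4.006%; the difference is below any observable
  effect on these data scales, and the value is configurable).
* `confusion_from_rates` inverts printed sensitivity/specificity into
  integer counts by nearest-integer (half-up) rounding. Printed rates are
  themselves rounded from integer counts, so this inversion reproduces the
  source counts whenever the printed precision is at least three digits.
* Youden threshold selection searches only over the observed
  probabilities; under the strict rule every distinct observed value is a
  distinct operating point, and ties take the smallest threshold.

## Metrics and bootstrap

Percent correct, F1, sensitivity and specificity are computed from the
thresholded confusion matrix; MAE and Brier score from raw probabilities;
AUC by the rank (Mann–Whitney) statistic with ties at one half. AUC is
*refused* for augmented diagnosis sets, whose values mix the machine scale
(centred near 4%) with the human scale (centred near 50%): ranks across
the two provenances are meaningless, so the container records per-case
provenance and the metric raises.

Confidence intervals use the plain percentile bootstrap over case-level
resamples with replacement, resample size = n, unstratified by default (a
stratified variant is available). Plain percentile rather than BCa because
the procedure being modelled is simple case resampling; the calibration
test below checks it is adequate at n = 50. Resamples on which a metric is
undefined (single-class draws for AUC/sens/spec) are redrawn and counted.
The paired comparison between two sources is a paired bootstrap: both are
evaluated on the same resample, and the two-sided p-value is twice the
fraction of resamples where the observed difference loses its sign
(10,000 resamples by default). This is one reasonable choice among several;
no claim is made that it matches any particular published test.

## Synthetic data generator

Real per-case study data is unavailable, so scenarios are generated from a
class-conditional logit-normal model. For a source with target
(sensitivity, specificity) at threshold t and spread σ:

```
logit(p) ~ N(mu_class, σ),   mu_pos = logit(t) + σ·Φ⁻¹(sens),
                             mu_neg = logit(t) − σ·Φ⁻¹(spec)
```

so the exceedance probabilities at t equal the targets exactly, at any
threshold. This closed form is what makes parameter-recovery tests sharp
(3 binomial SE at n = 10,000 per class).

Default scenario ("pilot-study"): 50 cases, exactly 20 positive / 30
negative; reader groups of 7 and 6; readers at sens 0.65 / spec 0.85 at the
50% cutoff with σ = 1 and between-reader location jitter of SD 0.25 on the
logit scale; a machine source at sens 0.90 / spec 0.767 at t = 4.008% with
σ = 0.8. The small machine σ compresses its probabilities near its low
threshold, reproducing the characteristic scale mismatch between machine
and human diagnoses and giving the deferral band (≈ a dozen of 50 cases in
[2.5%, 5.5%]) something to route.

**Shared case difficulty.** Readers additionally share a per-case random
effect on the logit scale (`case_difficulty_sd = 1.0`; the machine is not
affected). Reader locations are calibrated against the *total* spread
`sqrt(σ² + sd²)`, so each individual's marginal operating point still hits
its target exactly, while consensus aggregates can only average away the
idiosyncratic component. This matters: with independent reader errors a
7-reader consensus approaches perfection, which no reader study shows. With
the defaults the infinite-panel consensus operating point is sens ≈ 0.71 /
spec ≈ 0.93 — i.e. the gap between individual readers (0.65/0.85) and a
13-reader consensus is capped at realistic levels, and simulated swarm
sessions land near sens 0.69 / spec 0.91. Between-reader correlation
*structure* beyond this single shared effect (e.g. experience-dependent
difficulty) is not modelled.

What the synthetic experiments therefore show: that the pipeline's logic —
interpolation, aggregation, deferral, sweep, bootstrap — behaves correctly
and that the qualitative hybrid-beats-both phenomenon emerges whenever the
machine is the more sensitive and the humans the more specific source. What
they do not show: anything about radiograph images, reader behaviour beyond
the operating-point model, or the numeric values a particular clinical
dataset would produce.

## Deferral and sweep conventions

* Band membership is closed (`lo ≤ p ≤ hi`); "between 2.5% and 5.5%" is
  read inclusively. Configurable.
* Sweep selection balances by machine-*predicted* sign (which side of the
  machine threshold a case falls on), not by ground truth — routing must
  not peek at labels. A label-balanced variant exists for comparison.
* Distance to the threshold is measured in raw probability |p − t|; a
  logit-scale variant is available because the machine's probabilities are
  compressed near its threshold.
* The grid is k = 0, 2, 4, …, n; when one side runs out of cases the
  remainder is taken from the other side and the point is flagged
  asymmetric, so the final point always routes every case. Endpoint
  identities (k = 0 ≡ machine accuracy, k = n ≡ swarm accuracy) hold
  exactly by construction and are asserted in tests.
* With two reader groups the pipeline evaluates each group's swarm and
  pools group-level diagnoses by replicating each case per group
  (50 cases × 2 groups = 100 pooled diagnoses).

## Problem sizes and determinism

Every stochastic stage takes an explicit seed, and all session, bootstrap
and replicate seeds descend from a single master seed via seed sequences;
identical configurations produce byte-identical outputs. The shipped
experiments use 50-case scenarios, 1000-resample bootstraps, 500-replicate
coverage studies and 100–200-replicate end-to-end comparisons; these sizes
give sub-percent Monte Carlo error on the reported means while keeping any
single command in the tens of seconds on one CPU.

## Known limitations

* The swarm dynamics are a minimal surrogate; per-user conviction
  weighting, fatigue, anchoring and real-time social effects are out of
  scope, as is any graphical or networked front end.
* The paired bootstrap p-value is a pragmatic default, not an attempt to
  replicate any specific published significance test.
* Reported individual-average rows can be computed either from pooled
  diagnoses or as group means; with unequal group sizes these differ, and
  both variants are exposed rather than preferring one.
* `confusion_from_rates` assumes the printed rates round half-up from
  integer counts; two-digit rates on large n can be ambiguous.
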