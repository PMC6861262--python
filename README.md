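# swarmdx

Simulation and evaluation toolkit for **human-in-the-loop diagnostic
studies**: a headless model of real-time "swarm" consensus among expert
readers, crowd-aggregation baselines, diagnostic-accuracy metrics with
bootstrap inference, and a confidence-band deferral scheme that routes a
machine classifier's low-confidence diagnoses to the human swarm.

It is aimed at researchers in diagnostic test evaluation and selective
prediction who want to study — on fully synthetic, reproducible data — when
a hybrid human+machine system beats either component alone.

## The problem and the model

A binary diagnostic task (here framed as pneumonia on chest radiographs,
label 1 = disease) is attempted by three kinds of sources, each emitting a
per-case probability of disease:

* **Individual readers**, binarized at a 50% cutoff (strictly `p > t`).
* A **real-time swarm**: a panel of readers collectively steers a shared
  pointer among five probability bins — (0–5%], (5–25%], (25–65%],
  (65–85%], (85–100%] — on a unit circle. Each tick every agent pulls the
  pointer toward its intended bin with a unit force; the per-bin
  accumulated pull F(i) (force × time) is turned into a refined diagnosis
  by **squared-impulse interpolation** over the bin midpoints v_i:

  w_i = F(i)² / Σ_a F(a)²,  diagnosis = Σ_i w_i · v_i

* A **machine model** whose probabilities concentrate near a low
  discrimination threshold (default t = 4.008%, chosen by maximizing
  Youden's J = sensitivity + specificity − 1 on a validation set).

Machine models of this kind tend to be more *sensitive*, human consensus
more *specific*. The **augmentation model** exploits both: every case whose
machine probability falls in a closed low-confidence band around the
machine threshold (default [2.5%, 5.5%]) is deferred to the swarm, whose
diagnosis (binarized at 50%) replaces the machine's. A sensitivity sweep
generalizes the band, deferring 0…100% of cases in order of distance to the
machine threshold, balanced between machine-predicted positives and
negatives, with a 1000-resample 90% percentile-bootstrap accuracy band at
each grid point.

Because no case-level reader-study data is public, the `synthetic_data`
module generates calibrated scenarios from a class-conditional logit-normal
model: `logit(p) ~ N(mu_class, sigma)` with locations chosen in closed form
so that any target (sensitivity, specificity) at any threshold holds
exactly in expectation, plus a shared per-case difficulty effect that caps
how much a consensus of readers can outperform its members.

## Worked example

```python
import swarmdx as sx

# invert a printed operating point into counts on 20+/30- cases
cm = sx.confusion_from_rates(0.900, 0.767, n_pos=20, n_neg=30)
print(f"machine: {cm.tp + cm.tn}/50 correct = {sx.percent_correct(cm):.1f}%, "
      f"F1 = {sx.f1(cm):.3f}")

# synthetic 50-case study: 7-reader swarm session + confidence-band deferral
bundle = sx.pilot_study_scenario(seed=2)
swarm = sx.run_swarm_session(bundle.cases, bundle.groups["A"],
                             config=sx.SwarmConfig(seed=2))
plan = sx.route(bundle.ml, band=(0.025, 0.055), threshold=0.04008)
final = sx.augment_predictions(bundle.ml, swarm, plan)
print(f"{len(plan)} low-confidence cases deferred to the swarm")
for name, diag, t in [("machine ", bundle.ml, 0.04008),
                      ("swarm   ", swarm, 0.5),
                      ("deferral", final, 0.5)]:
    c = sx.confusion(sx.binarize(diag, t), bundle.cases)
    print(f"{name}  accuracy {sx.percent_correct(c):4.1f}%   "
          f"sensitivity {sx.sensitivity(c):.2f}   specificity {sx.specificity(c):.2f}")
```

prints

```
machine: 41/50 correct = 82.0%, F1 = 0.800
12 low-confidence cases deferred to the swarm
machine   accuracy 84.0%   sensitivity 0.90   specificity 0.80
swarm     accuracy 80.0%   sensitivity 0.75   specificity 0.83
deferral  accuracy 94.0%   sensitivity 0.95   specificity 0.93
```

On this replicate the machine is the more sensitive source (0.90), the
swarm the more specific one (0.83 overall, near-perfect on its confident
cases), and the deferral model inherits the better half of each — 94%
accuracy against 84% and 80% for the components alone.

The same flow is available from the shell:

```bash
swarmdx --seed 2 --out run synth                       # scenario CSV
swarmdx --seed 2 --out run swarm run/case_table.csv    # sessions + traces
swarmdx --seed 2 --out run evaluate run/swarm.csv --ml-column chexmax_like
swarmdx --seed 2 --out run augment run/swarm.csv \
    --ml-column chexmax_like --swarm-column swarm
swarmdx --seed 2 --out run sweep run/swarm.csv \
    --ml-column chexmax_like --swarm-column swarm
```

## Layout

| module | contents |
| --- | --- |
| `swarmdx.core_io` | `CaseSet`/`DiagnosisSet`, CSV/JSON I/O, `StudyConfig`, pipeline orchestration |
| `swarmdx.swarm_engine` | bin scheme, agent-based session simulator, squared-impulse interpolation |
| `swarmdx.classify_aggregate` | binarization, crowd mean/majority, Youden threshold, confusion matrices |
| `swarmdx.metrics` | percent correct, MAE, Brier, AUC, F1, sens/spec; percentile bootstrap; paired bootstrap test |
| `swarmdx.hitl` | confidence-band routing, augmentation, deferral-fraction sweep |
| `swarmdx.synthetic_data` | calibrated logit-normal scenario generator |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
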