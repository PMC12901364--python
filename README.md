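# careflow

Healthcare process mining from hourly clinical time series.

Hospital information systems record patient trajectories as sparse hourly
measurement tables, not as tidy event logs — yet the questions clinicians ask
("which pathways lead to sepsis?", "is cardiac damage the gateway to
multi-organ failure?") are questions about *processes*. `careflow` closes that
gap for ICU-style data: it turns hourly vital-sign/laboratory tables (the
PhysioNet Challenge 2019 pipe-separated dialect) into clinical-state event
logs, discovers the cohort's process map, scores the map's quality, renders
structured reports from aggregate artifacts only, and evaluates multi-rater
report scoring. It is written for clinical data scientists and
epidemiologists who want the whole chain — including a synthetic-cohort
generator with known ground truth — testable offline on one machine.

## What it computes

**Clinical-state abstraction.** Two disease-progression models map each
hour to an activity label:

- *infection*: SIRS temperature bands (T < 36 °C hypothermia, 36–37.5 °C
  normal, > 37.5 °C fever) crossed with a leukocytosis/leukopenia flag
  (WBC > 12 or < 4 ×10³ cells/µL) — 6 combined states plus the absorbing
  `Sepsis` label taken from the dataset (7 activities);
- *organ*: per-organ dysfunction flags (troponin I > 0.04 ng/mL cardiac,
  creatinine > 1.3 mg/dL renal, AST > 40 IU/L hepatic) aggregated from
  `Low Risk` through single- and two-organ damage to `Multiorgan Damage`
  plus `Sepsis` (9 activities).

Event-log construction runs five stages: validation (physiological bounds,
chronology, duplicate signatures), hourly classification with
last-observation-carried-forward, temporal-order verification, cohort
filtering (patients lacking any required variable are excluded), and
collapse of consecutive repeats, truncating at sepsis onset.

**Discovery.** The directly-follows graph (DFG) weights each edge (a, b) by
how often b immediately follows a; nodes carry case coverage (share of
traces containing the activity). The heuristics-miner dependency measure
(|a→b| − |b→a|)/(|a→b| + |b→a| + 1) scores edge direction. The process
matrix — the DFG in square-matrix form — is the only artifact that leaves
the pipeline for report generation.

**Conformance.** The DFG is converted to a state-machine workflow net and
replayed token by token. Fitness F = ½(1 − Σm/Σc) + ½(1 − Σr/Σp) counts
missing (m) and remaining (r) tokens against consumed (c) and produced (p);
precision P penalizes escaping arcs — model-enabled continuations never
observed; F1 = 2·P·F/(P + F). A flower model (everything allowed) scores
F = 1 but low P, which the harmonic mean punishes.

**Evaluation.** Reports are scored on six weighted criteria (clinical
accuracy 0.25, process-mining understanding 0.20, actionable insights 0.20,
statistical interpretation 0.15, structure & clarity 0.10, evidence-based
reasoning 0.10) on a 1–4 scale; agreement is Fleiss
κ = (p₀ − pₑ)/(1 − pₑ), consistency across cases Cronbach
α = (k/(k−1))(1 − Σσᵢ²/σₜ²), and cost-effectiveness the rounded ratio of
overall mean to per-report cost.

## Worked example

```python
import careflow as cf

spec = cf.infection_cohort_spec(n_patients=100, seed=42)
cohort = cf.simulate_cohort(spec)
log, report = cf.build_event_log(cohort, cf.StateModelSpec("infection"))
dfg = cf.discover_dfg(log)
result = cf.evaluate_conformance(dfg, log)
```

prints, via the report and DFG:

```
patients in/kept/excluded: 100/100/0
events: 1263, unique traces: 99
activities: 7, edges: 35
most frequent transition: Normal Temperature -> High Temperature (122)
Normal Temperature coverage: 98.00%
fitness=1.000 precision=1.000 f1=1.000
```

100 synthetic patients produce 1,263 state-change events in 99 distinct
pathway variants over the 7 infection-model activities; the busiest edge is
normothermia → fever, and `Normal Temperature` appears in 98 % of traces (a
central hub, as on real sepsis process maps). Replaying the log on its own
discovered model is perfect by construction — fitness, precision and F1
all 1.0 — which is the built-in self-consistency check; real modelling
questions compare *different* logs and models.

The same pipeline runs from the shell:

```bash
careflow run-all --model infection --n-patients 100 --seed 42 --out out/
careflow evaluate --ratings ratings.csv --out eval.json
```

## Layout

- `src/careflow/synthetic.py` — Markov ground-truth cohort generator, PSV export
- `src/careflow/eventlog.py` — event-log model, CSV/PSV readers, validation rules
- `src/careflow/states.py` — disease-state models, five-stage log pipeline
- `src/careflow/discovery.py` — DFG, variants, process matrix, DOT export
- `src/careflow/conformance.py` — state net, token replay, precision, F1
- `src/careflow/reporting.py` — prompt assembly, template reports, consensus
- `src/careflow/evaluation.py` — rubric, Fleiss κ, Cronbach α, cost ratios
- `src/careflow/benchmark.py` — published evaluation tables used as inputs
- `src/careflow/cli.py` — `careflow` command group
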