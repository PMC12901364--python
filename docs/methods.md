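# Methods

This note documents the models, conventions and numerical choices behind
`careflow`, in the spirit of a statistical package's model documentation:
what is computed, under which assumptions, and where the genuinely open
design decisions were resolved.

## Clinical-state models

Both disease models classify one patient-hour at a time from measurement
values and emit an activity label.

**Infection model (7 labels).** Temperature follows SIRS bands. The normal
band is the *closed* interval [36.0, 37.5] °C; hypothermia is strictly
below 36.0 and fever strictly above 37.5, reading the clinical definitions
("<36", "36–37.5", ">37.5") literally. The infection flag is WBC > 12 or
WBC < 4 in the dataset's native unit of 10³ cells/µL (thresholds quoted in
cells/L in some sources are a typographical slip; the dataset column is in
10³/µL). An infected, non-septic hour gets the combined label
`Infection + <temperature state>`; the dataset's Sepsis-3 label overrides
everything. Universe: 3 plain temperature states, 3 infection-combined
states, `Sepsis`.

**Organ-damage model (9 labels).** Cardiac (troponin I > 0.04 ng/mL),
renal (creatinine > 1.3 mg/dL) and hepatic (AST > 40 IU/L) dysfunction
flags combine to `Low Risk` (0 flags), three single-organ labels, three
pair labels (`Renal + Cardiac Damage`, `Liver + Cardiac Damage`,
`Renal + Liver Damage` — the third pair named by analogy with the first
two), `Multiorgan Damage` (all three) and `Sepsis`.

All comparisons are strict inequalities against the thresholds; values
exactly at a threshold are non-pathological. Thresholds are configurable
per model spec (YAML/JSON) but the defaults above are the model.

## Event-log pipeline

Five stages, in order:

1. **Validation.** Mandatory attributes (case, activity, timestamp),
   strict chronological ordering, duplicate event signatures (exact
   (case, activity, timestamp) equality — the strictest reading),
   admission-before-discharge where both exist, and physiological bounds:
   a core temperature above 45 °C is a measurement artifact. Flagged items
   are excluded and itemized, never repaired.
2. **Hourly classification with LOCF.** Laboratory values are sparse; a
   per-hour state is undefined without a fill rule. Each required variable
   carries its last observation forward after its first measurement
   (last observation carried forward); hours before every required
   variable has been seen emit no state. Artifact values (Temp > 45 °C)
   are treated as missing, so the previous valid observation carries
   through them. This is the minimal assumption that makes hourly
   evaluation of sparse labs well-defined; it is also the main lever on
   reproduced cohort counts from real data — evaluating only freshly
   measured hours yields fewer events and different trace counts, so any
   count comparison must state the fill rule.
3. **Temporal-order verification** on the constructed log (defensive;
   construction already sorts stably, ties preserved in input order).
4. **Cohort filtering.** A patient is included iff every required variable
   (Temp+WBC for infection; creatinine+troponin+AST for organ) has ≥ 1
   recorded value over the stay. Exclusions are counted and named in the
   stage report.
5. **Collapse and truncation.** Consecutive identical labels collapse to
   the first occurrence (traces record *state changes*); with an absorbing
   sepsis label, a single `Sepsis` event terminates the trace at the first
   labelled hour.

The stage report (patients in/kept/excluded, events, unique traces) is the
pipeline's accounting contract: in = kept + excluded always holds.

## Synthetic cohorts

The generator emulates the hourly-ICU-table shape of the data the pipeline
targets: one pipe-separated file per patient with the PhysioNet Challenge
2019 header (41 columns), hourly rows indexed by ICULOS starting at 1, a
binary absorbing SepsisLabel, and NaN for every unmodeled column.

Dynamics are a first-order Markov chain over latent clinical states,
sampled hourly from a row-stochastic transition matrix; the initial state
defaults to the first state with probability 1 (clinical process maps show
a dominant single entry point), configurable. Each state emits the five
modeled variables (Temp, WBC, TroponinI, Creatinine, AST) *uniformly*
within per-state intervals chosen strictly inside the classification bands
of the state they represent — so with zero missingness, classification
recovers the latent path exactly (the emission-soundness property the
tests assert). Each scheduled measurement is independently missing with a
configurable rate (default 0.3 — labs in ICU tables are sparse). Sepsis is
a separate absorbing *label*, not a latent state: each state has a
per-hour hazard, and onset truncates the record, mirroring datasets that
run "up to sepsis onset or discharge".

Default study conditions: the bundled infection and organ specs use 6
latent states each, self-loop-heavy transition matrices (diagonal 0.65–0.8),
hazards between 5·10⁻⁴ (low-risk states) and 0.02 (multi-organ), a
48-hour horizon, and 2,000 patients for parameter-recovery checks — the
scale at which every frequent transition accumulates ≥ 25 expected counts.

Reproducibility: patient *i* draws from `SeedSequence([seed, i])`, so a
cohort is bit-identical under a fixed spec and the first n patients are
stable when the cohort grows. Seeding with the (seed, index) pair rather
than their sum avoids stream collisions between (seed 1, patient 2) and
(seed 2, patient 1).

What the generator does **not** emulate: physiological autocorrelation and
trends, correlated multivariate noise, treatment effects, informative
missingness, inter-hospital heterogeneity. Passing recovery tests on this
generator therefore demonstrates correctness of the *pipeline arithmetic*
(classification, collapse, counting), not clinical validity on real data.

## Discovery and conformance

The DFG counts adjacent activity pairs per trace, trace starts/ends, and
case coverage (fraction of traces containing each activity — the
percentage annotation on process-map nodes; edge labels are absolute
counts). No frequency pruning is applied by default; a minimum-count edge
filter exists but is off. The dependency measure is the classical
heuristics-miner form (a − b)/(a + b + 1).

**State net.** Replay needs an executable model; the package derives a
state-machine workflow net from the DFG: one place per activity ("a just
executed") plus a single-token source and a sink; one visible transition
per activity, fireable from place a exactly when edge (a, b) was observed;
invisible start/end transitions wired from the observed start/end support.
Invisible transitions are excluded from enabled sets and token tallies.

**Token replay.** Standard accounting: the initial source token counts as
produced, the final sink consumption as consumed; a non-enabled firing
inserts a missing token; leftover tokens are remaining. When a firing
could consume from several places, the place of the most recently produced
token is preferred (deterministic, and in well-fitting replays the only
live token). Unknown activities replay as missing without crashing.
Fitness aggregates tallies over the whole log and then applies the
formula (log-level aggregation, not a mean of per-trace fitness values).

**Precision.** Escaping-arcs style: walk the observed prefixes, weight by
occurrence, and compare the model's enabled set against the activities
actually observed next. Prefix states are abstracted to their **last
activity** (order-1 abstraction). This matches the memorylessness of the
DFG-derived net and gives the clean calibration point that any log scores
precision 1 against its own DFG net; with full-prefix states that property
fails whenever two different histories share a last activity but differ in
continuation, which would make "perfect" models look imprecise for reasons
the net cannot express. Trace-end states contribute nothing (ending is
routed through invisible transitions). F1(0, 0) = 0 by convention.

## Reporting and consensus

Prompts are assembled deterministically from five components (role, task,
context with the enumerated valid states and a reversibility note, output
format, quality criteria); the payload is the serialized process matrix
plus aggregate statistics — by construction no patient identifier can
appear in a prompt or report. Reports follow a fixed six-section Markdown
skeleton; the three mandatory summaries (Case/Activity/Trace) live inside
*Data Summary Tables*, which lets both structural requirements hold
simultaneously. The interpreter contract is minimal (identity, generate,
cost); the shipped backends are a deterministic template renderer and a
scripted test double — live-API adapters satisfy the same contract but are
deliberately outside the test surface.

Consensus voting matches findings *textually* after normalization
(lowercase, whitespace collapse, numbers rounded to 2 significant
figures); findings supported by ≥ quorum backends are consensus, the rest
are preserved as divergent with provenance. Semantic clustering of
findings is explicitly not attempted — divergence is information, and a
normalization that silently merged near-statements would hide it.

## Evaluation layer

Weighted scores are Σ wᵢsᵢ over the six-criterion rubric (weights sum to
1; scale 1–4). The overall mean per model is the unweighted mean of its
per-case means, rounded half-up to 2 decimals — the convention that
reproduces the published ranking table rows exactly. Fleiss κ is computed
per criterion (items = reports, categories = 1–4) plus a pooled variant,
since either could be the single reported number; missing cells are an
error, never imputed. Cronbach α treats the cases as the k items. A rater
whose scores never vary carries no agreement information and can be
excluded (logged). Confidence intervals for overall means use a
nonparametric bootstrap over cases (2,000 resamples, seeded) — with k = 4
cases these are descriptive, not inferential. Performance-to-cost is
round(mean/cost) to the nearest integer, half away from zero.

The published benchmark tables (per-case scores, per-report costs) ship as
*inputs* in `careflow.benchmark`; ratios, totals and overall means are
always recomputed. For a few models the published overall mean differs
from the re-rounded mean of the printed per-case values by ≤ 0.02
(evidently computed before rounding); cost ratios therefore take the
published mean as their input rather than the recomputed one.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 40–150 patients for functional
checks and 2,000 patients × 48 h for statistical recovery — the size at
which every frequent transition reaches the ≥ 25 expected-count regime for
a 3-standard-error binomial comparison. Transitions into the absorbing
sepsis label compete with ordinary transitions, so recovery compares
row frequencies renormalized over non-sepsis successors against the
collapsed-chain truth P(i→j)/(1 − P(i→i)). All randomness flows from
explicit seeds; property-based tests run derandomized.

## Known limitations

- LOCF is a modelling choice, not ground truth; real-data cohort counts
  are sensitive to it (see pipeline stage 2).
- The DFG→net conversion and the precision estimator are one admissible
  pair among several in the conformance literature; numbers are comparable
  within this package, not across tools with different conversions.
- Findings consensus is textual; two backends phrasing one insight
  differently count as divergent.
- The evaluation layer's κ/α describe rater consistency, not correctness
  of what the raters scored.
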