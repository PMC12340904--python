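# Methods

## Data model

All events are indexed by **patient age in days** (real-valued). Raw tables
may declare their native unit per table (`days`, `months`, `years`); values
are converted on load with 1 month = 30.4375 days and 1 year = 365.25 days,
so "3 months" as a clustering window is 91.3125 days. We chose age-at-event
rather than calendar dates because it is the natural de-identified time
axis for real-world data and makes cross-patient alignment trivial.
Intervals are closed `[start, end]`; a missing end time makes a zero-length
point event.

Rows that fail validation (unparseable or negative times, end before start,
empty patient id) are **dropped and logged**, never fatal: observational
data are of inconsistent quality, and the rejection log is a first-class
output so the analyst can audit what was excluded. The identity
`rows in = events out + rejections` is enforced by a property test.

Per-patient anchors: diagnosis age (earliest Diagnosis event), death age
(earliest Death event), and last-contact age. When no explicit LastContact
event exists, last contact falls back to the maximum observed event end for
that patient — a conservative censoring time that can only shorten, never
extend, follow-up. An explicit LastContact event overrides it.

The patient-identifier column defaults to `patient_id` and is configurable,
since real exports never agree on its name.

## Line-of-therapy clustering

Treatments are clustered per patient by **start time only**: treatment
start is the clinical decision point, and a long infusion interval should
not extend the recruitment window. Two semantics are provided because "a
window" is genuinely ambiguous:

- **anchor** (default): the earliest unassigned start s₀ seeds a line that
  absorbs every start ≤ s₀ + w, then the rule recurses. This matches the
  common line-of-therapy convention of a fixed induction window and is
  insensitive to chains of closely spaced starts.
- **gap**: a start joins the current line if within w of the line's latest
  member start; chains can extend a line indefinitely.

The window boundary is inclusive (a start exactly at s₀ + w joins); ties at
identical start times join the earlier-seeded line. Both modes are verified
exhaustively against a brute-force evaluator of the textual rule for all
small patients, and satisfy: partition (every treatment in exactly one
line), monotonicity (more window, never more lines), and the limits w → ∞
(one line) and w → 0⁺ (one line per distinct start).

Re-administration of a drug beyond the window starts a new line; we do not
attempt maintenance-therapy semantics.

Regimen labels are the sorted, lower-cased, de-duplicated agent names
joined by `+`, giving Sankey nodes and grouping keys a canonical identity.

## Endpoint derivation

Endpoints are declarative: a start rule (diagnosis, first treatment from a
name set, line *k*, or first line with a given regimen) plus an ordered
list of event matchers.

- OS: diagnosis → death.
- Time-to-treatment-end: treatment start → next line, labeled toxicity, or
  death.
- rwPFS: treatment start → next line, radiological progression or
  metastasis, pathological recurrence, or death.

"Change in treatment line" is resolved **structurally** — the start of line
k+1 relative to the index line k — rather than by name matching, so it is
consistent with whatever clustering produced the lines. Progression /
metastasis / recurrence are matched by case-insensitive substring patterns
(defaults `progress`, `metasta`, `recurren`) over the response-type
categories, because real-world vocabularies differ per institution; the
patterns are part of the endpoint configuration and should be set to the
local dialect (e.g. add `pd` where bare "PD" is used).

The endpoint is the earliest qualifying event **strictly after** the start:
the open lower bound excludes zero follow-up and immortal-time artifacts;
patients whose start is unresolvable or whose last contact is not after the
start are excluded with a logged reason rather than silently dropped. Ties
at the same day are broken by matcher order, with Death placed last by
default so a same-day progression is recorded as progression.

## Survival statistics

- **Kaplan–Meier**: product-limit over distinct event times; censored
  observations tied with an event time count as at risk for that time and
  are removed afterwards (the usual censoring-after-events convention —
  stated explicitly because it changes small-sample results). Median =
  smallest event time with Ŝ ≤ 0.5, no interpolation. Greenwood variance
  for standard errors.
- **Log-rank**: K groups, quadratic form (O−E)ᵀV⁻¹(O−E) on the first K−1
  groups (pseudo-inverse for safety), hypergeometric variance per pooled
  event time, chi-square reference with K−1 df. Event times where only one
  subject remains contribute no variance.
- **Cox**: damped Newton from β = 0 on the Breslow (default) or Efron
  partial likelihood; Efron matters because day-granularity data tie
  heavily. Risk-set sums are reverse cumulative sums over the time-sorted
  sample. Convergence requires both max|gradient| < 1e−8 and a vanishing
  Newton step: with a monotone (separated) likelihood the gradient
  underflows while the step stays O(1), so requiring both lets the
  iteration keep diverging until the |β| > 50 bound flags non-convergence
  instead of reporting a spurious optimum. The step-halving accept margin
  is relative to |log-likelihood| so float noise near the optimum cannot
  stall the iteration. Standard errors from the inverse observed
  information; 95% CI = β̂ ± 1.96·SE. A constant covariate raises a
  degenerate-information error.
- **Fisher's exact test**: two-sided p sums hypergeometric probabilities no
  larger than the observed table's, computed with exact integer weights
  C(r₁,x)·C(r₂,c₁−x), so the comparison is exact rational arithmetic with a
  single float conversion at the end. Odds ratio (a·d)/(b·c), infinite when
  b·c = 0 with a·d > 0.

p-values are reported at full float precision; rounding is presentation.

## Cohort analytics

Sankey nodes are (line index, regimen) with **patient** counts; for every
node, count = outgoing links + terminal patients (conservation is a tested
invariant). Regimens below `min_node_size` patients at a line collapse into
an `other` node (default 1 = no collapse). The agent × line heatmap counts
**distinct patients** per cell (a combination line increments each of its
agents); event-level counting would double-count multi-cycle regimens.
Duration outliers use the Tukey upper fence (duration > Q3 + 1.5·IQR,
strict) within regimen groups of ≥ 4 lines — upper tail only, since the
question is *extended* regimens; smaller groups are never flagged. Swimmer
lanes default to absolute age with opt-in re-zeroing to each patient's
first treatment. Quantiles use the default linear-interpolation convention
of numpy.

## Synthetic cohorts

The generator emulates a small neoadjuvant muscle-invasive bladder-cancer
cohort: 51 patients by default, diagnosis age uniform 45–82 years,
first-line cisplatin+gemcitabine vs carboplatin+gemcitabine at 2:1,
true log hazard ratio 0.7 against the carboplatin-based arm (carboplatin is
typically given to frailer patients, hence the worse-prognosis arm),
baseline hazard 1/400 per day (median time-to-progression ≈ 9 months in the
reference arm), exponential censoring at 1/1500 per day (about one in five
lost before progressing), progression:death failure split 0.7:0.3.
A Weibull shape parameter generalizes the exponential when non-constant
hazards are wanted.

Separation is built in: within-line agent starts are jittered ≤ 14 days
(< half the 90-day window) while consecutive line starts are ≥ 200 days
apart (> 2 windows), so the clustering recovers the designed partition
exactly — this is the construction the end-to-end recovery tests rely on.
Subsequent lines start only after the progression report, as second-line
therapy follows progression clinically; this also makes the generated rwPFS
endpoint times follow the proportional-hazards law exactly, so the Cox
recovery check is well-posed. Progression vocabulary includes dialect noise
("Progression", "progressive disease", "PD", "Metastasis", "metastatic
lesion", "Recurrence"); the recovery configuration declares the `pd`
pattern explicitly because the defaults intentionally do not match the bare
abbreviation.

What passing these tests shows: the pipeline is internally correct and
recovers a known truth under clean, separated timing. What it does not
show: robustness to overlapping lines, misrecorded dates, or vocabulary the
matchers were not configured for — real deployments must tune the window
and patterns to their dialect.

## Problem sizes

The acceptance checks use: exhaustive clustering-oracle agreement for all
patients of ≤ 6 treatments on an 80-day start grid in [0, 400] (both modes,
two windows); 1,000 random cohorts for monotonicity/limits; 100 random
datasets each for the KM cross-checks; 200 replicates of n = 500 for Cox
CI coverage with a 1e−4 grid-search agreement spot-check; every 2×2 table
with grand total ≤ 40 for Fisher; 1,000 random timelines for endpoint
dominance; 500 random cohorts for Sankey conservation; and 20 seeds of
n = 1,000 for end-to-end recovery. These sizes give stable checks at
interactive runtimes.

## Known limitations

- No changepoint/disease-stage inference from longitudinal measurements.
- No dose-change or drug-substitution semantics within a line.
- Toxicity endpoints fire only on explicitly labeled toxicity events — no
  adjudication or grading.
- Free-text inputs are out of scope; tables must already be structured.
- No time-varying covariates, stratified Cox, or competing-risks
  estimators.
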