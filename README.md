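# rwevents

Real-world clinical data (EHR extracts, registry exports) arrive as a pile
of heterogeneous longitudinal tables — medications, imaging reads, pathology
reports, vital status — each with its own columns and vocabulary.
`rwevents` is a headless library + CLI for turning such tables into
analysable survival data: it harmonizes everything into a single
patient-age-indexed event stream, clusters temporally proximal treatment
events into **lines of therapy**, derives real-world survival endpoints
(overall survival, time-to-treatment-end, real-world progression-free
survival, rwPFS), and runs the survival statistics and cohort visual
analytics (Sankey treatment-flow graphs, swimmer plots, duration outliers)
from first principles.

It is aimed at clinical data scientists and biostatisticians who need
reproducible, scriptable endpoint derivation from routine-care oncology
data — the kind of analysis usually done interactively, done here as code.

## The core methods

**Line-of-therapy clustering.** Treatment events whose *start* times fall
within a user-defined window are grouped into one line. Two window
semantics: *anchor* (a line seeded at the earliest unassigned start s₀
absorbs every start ≤ s₀ + w) and *gap* (a start joins the current line if
within w of the line's latest member start). Each line gets a canonical
regimen label (sorted, case-normalized agent names joined by `+`).

**Endpoint derivation.** Declarative start/endpoint rules: OS runs from
diagnosis to death; TTE and rwPFS run from a treatment start to the earliest
of next-line start (resolved structurally from the line partition),
radiological progression/metastasis, pathological recurrence, or death —
each detected by configurable case-insensitive name patterns over
response-type events. Censoring is at last contact; endpoints strictly
after the start, so no immortal time and no zero follow-up.

**Survival statistics**, implemented in-repo and cross-checked against
reference implementations in the test suite:

- Kaplan–Meier product-limit estimator Ŝ(t) = ∏_{tᵢ≤t} (1 − dᵢ/nᵢ) with
  Greenwood standard errors,
- K-group log-rank test (O−E)ᵀV⁻¹(O−E) with hypergeometric variance,
- Cox proportional hazards h(t|x) = h₀(t)·exp(βᵀx), damped Newton on the
  partial likelihood, Breslow or Efron ties,
- Fisher's exact test by exact integer hypergeometric enumeration.

A seeded synthetic-cohort generator (`rwevents.simulate`) emulates a
neoadjuvant bladder-cancer cohort (platinum-doublet first lines, diverse
later lines, progression/death/censoring with a configurable log hazard
ratio) and carries its ground truth, so the entire pipeline is testable
without any patient data.

## Worked example

```bash
rwevents simulate --n 60 --seed 42 --out-dir raw
rwevents build   --params raw/params.tsv --out events.tsv
rwevents cluster --events events.tsv --window 3mo --out lines.tsv
rwevents survive --events events.tsv --lines lines.tsv \
                 --endpoint rwpfs --group line1_regimen --out survival.tsv
rwevents km      --survival survival.tsv --out km.tsv
rwevents cox     --survival survival.tsv --covariates group
```

prints

```
log-rank chi2=13.7761 df=1 p=0.0002059
group carboplatin+gemcitabine: n events 17, median 86 d
group cisplatin+gemcitabine: n events 24, median 410 d
group coded 0=carboplatin+gemcitabine 1=cisplatin+gemcitabine
group: coef=-1.1697 HR=0.3105 se=0.3318 95% CI [-1.8200, -0.5193]
log partial likelihood -122.3564 (breslow ties, converged=True, 5 iterations)
```

Reading: with a 3-month clustering window the 60 simulated patients split
into carboplatin+gemcitabine and cisplatin+gemcitabine first lines; the
carboplatin-based arm has a much shorter median rwPFS (86 vs 410 days), the
log-rank test rejects equality of the survival curves (p ≈ 2·10⁻⁴), and the
Cox hazard ratio of 0.31 for the cisplatin arm (equivalently ≈ 3.2 against
carboplatin) quantifies the difference. `rwevents sankey` and
`rwevents swimmer` produce the corresponding cohort visual-analytics
tables/JSON.

The same pipeline is available as library calls (`parse_parameter_file`,
`build_event_table`, `build_timelines`, `cluster_cohort`,
`cohort_survival_table`, `km_by_group`, `logrank_test`, `cox_ph`, …); see
the module docstrings.

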