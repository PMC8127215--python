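# Methods

## The model

`rarecareer` answers a simple quantitative question: across an entire clinical
career, how many patients with each of a long list of conditions — common to
extremely rare — does a clinician, and a whole graduating cohort, encounter?

### Disease list

The theoretical list assigns condition code numbers (CCN) 1..N and a prevalence

    p(c) = p_max · exp(−k·(c − 1)),   k = ln(p_max / p_min) / (N − 1)

anchored so that p(1) = p_max and p(N) = p_min exactly. With the defaults
(p_max = 0.641, p_min = 1e−6, N = 462) the curve passes through the 2e−3
rare-disease threshold at code 200, 1e−4 at code 303 and 1e−5 at code 382,
all within 2% relative. The single-rate form is the simplest curve consistent
with those five anchors; a fitted-constant variant would be indistinguishable
at this precision. Exactly `n_congenital` (default 73) codes are drawn
uniformly without replacement and labelled congenital/persistent; the rest are
spontaneous. Users may instead supply their own CSV of real conditions
(`code,prevalence,acquisition_class`), bypassing the curve.

### Career simulation

For each clinician (outer loop) and each condition (inner loop):

- **Local jitter.** Prevalence is perturbed once per (clinician, condition)
  by a uniform relative factor in ±`jitter_fraction` (default 0.15), held
  constant over the career — a fixed local-demographics effect, not yearly
  noise. The perturbation has zero mean, so expectations are unchanged.
- **Spontaneous conditions** arise anew in the standing panel each year:
  yearly count ~ Binomial(panel_size, p′), independent across years.
  Prevalence is deliberately used as a per-year encounter probability — the
  classic desk arithmetic (one case per year of a 1/2000 condition on a
  2000-patient panel) does exactly this, conflating prevalence with annual
  incidence; the package inherits rather than introduces that convention.
- **Congenital/persistent conditions** are carried lifelong, so they can only
  be *first* met in patients newly entering the panel: the whole panel in
  year 1 and in practice-change years, otherwise the attrition-replacement
  fraction `round(attrition_rate · panel_size)` (half away from zero).
  Newly encountered cases accumulate into an active caseload, reset to the
  fresh draw at each practice change (default `congenital_loss =
  job_change_only`). An `attrition_also` mode additionally removes each
  carried case with probability `attrition_rate` per year, for users who want
  caseload conservation with panel turnover. The caseload is capped at
  `panel_size`. `CaseCube` stores both the per-year caseload (`counts`,
  patient-years) and the newly-acquired counts (`new_counts`, unique
  patients); totals default to unique patients, and both are exported.
- **Practice changes.** Each clinician draws a number of changes uniformly on
  [`min_job_changes`, `max_job_changes`] and the change years uniformly
  without replacement from {2..years}.

### Sampling modes

`binomial` (default) draws Binomial(n_exposed, p′) — the exact patient-level
interpretation. `expected_branch` reproduces an alternative branching on
whether the expected count λ = n_exposed·p′ is below one: floor(λ) certain
cases plus a Bernoulli(λ − floor λ) extra (for λ < 1 this is Bernoulli(λ)).
Both have mean n_exposed·p′, so all expectation-based checks hold in either
mode; variances differ (the branch mode is underdispersed).

### Expectations oracle

Expected counts are linear: annual = p·panel, career = p·panel·years,
cohort = p·panel·years·clinicians. No finite-panel depletion or ≥1-case
probability correction is applied — the oracle mirrors the simulator's
assumptions so that simulated means converge to it exactly.

### Survey analysis

Ordered Likert counts from two independent surveys (before/after) are
collapsed into a 2×2 table at a chosen split and tested with Pearson's
chi-squared (df = 1), continuity correction off by default (for the bundled
table both corrected and uncorrected give p < 1e−6, so the choice is
immaterial there); relative percentages are reported per survey column at one
decimal. The two surveys are treated as unpaired: respondents were anonymous
and response totals differ (89 vs 77).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_clinicians` | 97 | cohort size |
| `years` | 30 | career length (years) |
| `panel_size` | 1500 | patients per clinician (≈2000 medical, ≈1500 dental) |
| `min/max_job_changes` | 2 / 10 | practice changes per career |
| `attrition_rate` | 0.10 | yearly fraction of the panel replaced |
| `jitter_fraction` | 0.15 | max relative prevalence perturbation |
| `sampling_mode` | binomial | yearly case-count law |
| `congenital_loss` | job_change_only | how a congenital caseload can shrink |

`attrition_rate` has no canonical source value; 0.10/year is a plausible
primary-care panel turnover, and the headline quantities (first-year and
spontaneous arithmetic) are insensitive to it — it only shapes how quickly
congenital caseloads grow between practice changes.

## Randomness and reproducibility

A single master seed drives everything. Each clinician uses an independent
substream seeded by `SeedSequence((seed, clinician_index))`, so identical
inputs give bit-identical case cubes and enlarging the cohort never perturbs
earlier clinicians. The CLI writes a manifest (config snapshot, seed,
disease-list fingerprint) from which any run replays bit-exactly.

## Numerical choices

- Disease-list CSVs are written with `%.17g` and read with pandas'
  `round_trip` float parser, so a list round-trips bit-exactly.
- Attrition patient counts round half away from zero.
- Jittered prevalence is clamped to [0, 1]; case counts are capped at the
  exposed pool.
- Indices are 1-based throughout (CCN, clinician, year of practice).

## What the defaults do and do not emulate

The default configuration reproduces classroom-scale cohorts (95–97
clinicians, 30–40 year careers, 1500-patient panels). It does not model:
specialist referral patterns, variable panel sizes, career interruptions,
within-panel patient ageing, or real disease prevalences (the theoretical
exponential list is a stand-in until curated prevalence tables exist — the
`DiseaseList.from_csv` path is the hook for them). Passing tests therefore
demonstrate internal statistical correctness (means match the linear oracle,
congenital bookkeeping follows the stated rules), not epidemiological realism
of any specific disease.

Problem sizes in the test suite are chosen for statistical power at desk
scale: the replicate study of the first-year class answer uses 1000 replicate
seeds (SE ≈ 0.12 on a mean of 14.25), and structural properties are checked
on small cohorts plus one full default-size run.

## Known limitations

- Prevalence doubles as annual encounter probability for spontaneous
  conditions; for chronic non-congenital diseases this overcounts re-visits.
- Congenital totals in `counts` are patient-years, not unique patients; use
  `new_counts` (the default for totals) for unique patients.
- The unpaired survey test ignores respondent attrition between surveys;
  anonymous collection precludes a paired analysis.
- The expected-branch sampling mode matches the binomial in mean but not in
  variance; variance-sensitive conclusions should use `binomial`.
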