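# Methods

This note documents the models and procedures behind `medconcord`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions used throughout.

## Data model

The five input tables mirror the slice of a clinical common data model that
a prescribing/dispensing comparison touches.  Time is represented as
**integer day offsets** rather than calendar dates: the matching rule and
the age bands only ever need relative days, and day offsets are what
network data-sharing agreements typically permit.  In the synthetic
cohorts the per-patient origin is birth, so a record's day offset *is* its
age in days; age in months uses a mean month of 30.4375 days.  Age bands
are 0–<6, 6–<12, 12–<24, 24–<60 and 60–≤132 months, with 24–<60 the
reference (it holds the most records in pediatric cohorts).

Medication identity is the triple **(spectrum, class, name)**.  Spectrum is
dichotomous: penicillin, amoxicillin and dicloxacillin are narrow; all
other agents, including combinations such as amoxicillin/clavulanate, are
broad.  The bundled lexicon is deliberately synthetic — 15 antibiotic
classes with representative agents, each with a paired pseudo-RxNorm and
pseudo-NDC code — and is validated at load time (one class and spectrum per
name across code systems; the narrow-set rule enforced).  Real
vocabularies load through the same CSV schema.

## Cleaning

* **Same-day annotation.** Each medication record inherits the
  highest-priority encounter type of its day under IP > ED > AV > OT > UN,
  and the lowest (most antibiotic-appropriate) infection tier diagnosed
  that day.  Both priorities are design choices for situations the
  cleaning rules leave open; the IP-first order is conservative, ensuring
  any inpatient/ED contact that day triggers the exclusion below.
* **Inpatient/ED exclusion.** Institutions differ in their ability to see
  medications given in hospital or ED settings, so records tied to those
  encounters are removed, leaving ambulatory and unknown/missing settings.
  The stage is a pipeline toggle (`apply_enc_filter`) because some
  summaries are meaningful without it.
* **Same-day de-duplication.** One record per (patient, day, stream).  The
  broadest-spectrum agent survives; ties break lexicographically by class
  name then record id, making the survivor invariant under input row
  order.  De-duplication is per stream, since matching is what links the
  streams.

## Matching

Directional, windowed, one-to-one.  Sources are processed in
(day, record id) order; each takes its eligible target — same patient,
same medication specification, fill 0..7 days after the order — with the
smallest day gap, ties broken by earliest target day then target id, and a
consumed target is unavailable to later sources.  The window is inclusive
at both ends: same-day fills dominate real data and day 7 is the stated
boundary.  Consumption (one-to-one assignment) prevents double counting
and keeps the per-record binary flag well defined; it can be disabled
(`consume_targets=False`) to study one-to-many eligibility, which affects
well under 1% of records at realistic densities.  The unit and acceptance
suites check the grouped/sorted implementation against a naive
full-scan oracle implementing the same sequential rule, across hundreds of
random small instances; a *global* minimum-total-gap assignment is a
different (and not the stated) objective, which is why the oracle encodes
the per-source rule rather than an LP.

## Agreement statistics

Match rates are percentages rounded half-up to one decimal (kappa to two,
odds ratios to two), matching epidemiological table conventions.
Per-patient record counts are binned 0/1/2/3/4+ — the 4+ bin keeps the
5×5 table dense in cohorts where a few patients have many courses — and
every patient in the stratum contributes a cell, including (0,0).

Weighted kappa uses **linear (Cicchetti–Allison) disagreement weights by
default**, quadratic (Fleiss–Cohen) by option.  The computation and its
asymptotic variance (Fleiss–Cohen–Everitt form) come from
`statsmodels.stats.inter_rater.cohens_kappa`; the test suite re-derives the
statistic from the definition independently.  The 95% CI is normal-theory
on the kappa scale, truncated to [−1, 1], and collapses to the point
estimate if the variance is degenerate (e.g. an empty marginal).
Landis–Koch labels use upper-inclusive half-open bands — (0.20, 0.40] is
"fair", etc. — because the conventional printed bands leave the gaps
between 0.20/0.21 and so on undefined.

## Exposure classification

Dispensing is the reference: a patient with at least one fill is truly
exposed.  Cells are TP/TN/FN/FP as usual; the analysis window
(0–132 months by default) is applied to record ages before classification.
Specificity is **suppressed for open-system strata** by default: where
dispensing capture is incomplete, a "false positive" may simply be a fill
the data never saw, so the quantity is unverifiable rather than zero.
Confidence intervals for sensitivity/specificity are deliberately not
computed (an extension point, not a default output).

## Missingness models

Both models are logistic regressions on binary outcomes with clustered
data: record-level (dispensing without a matching prescription; covariates
race, Hispanic ethnicity, sex, age band, same-day encounter type, tier,
spectrum; repeated records per patient, patients within institutions) and
patient-level (false-negative; sex, race, ethnicity, chronic condition,
preterm, asthma, encounter-count quartiles).  Reference levels are White,
non-Hispanic, male (female for the patient-level model, matching the
male-vs-female contrast convention there), 24–<60 months, ambulatory
visit, Tier 1, broad spectrum, and Q1 utilization.

**Estimation default: maximum-likelihood logit with cluster-robust
(sandwich) standard errors on the institution id.**  The natural
hierarchical alternative — nested random intercepts for patient within
institution — has no deterministic ML fitter for binary outcomes in the
scientific Python stack; the variational approximation that exists
produces biased point estimates on exactly the strong-effect covariates
these models exist to estimate.  The robust-SE fixed-effects logit is the
standard terminal fallback for that chain, is deterministic, and recovers
planted effects with nominal coverage in the package's own simulations
(mean log-OR bias < 0.01 and 94% CI coverage at n = 20,000, 50
replicates).  `method="gee"` (exchangeable correlation within patient) and
`method="mixed"` (variational institution intercept) remain available; the
`ModelFit.method` tag records what produced each table.  Caveat: with very
few clusters (the bundled profiles have two institutions) sandwich
standard errors are themselves noisy; interpret per-term CIs from such
runs qualitatively.  Wald CIs are reported on the OR scale; two-sided
p < 0.05 flags significance; no multiple-testing adjustment is applied.
Encounter-count quartiles are computed from the stratum's data by default,
with fixed cuts (≤20 / 21–30 / 31–45 / 46+) as an option.

VIFs are computed as 1/(1−R²) on the dummy-expanded design; a perfectly
collinear column reports infinity rather than raising.

## Synthetic cohort generator

The generator emulates the observation process of a multi-institution
network extract:

* **Courses.** Each patient has a negative-binomial number of antibiotic
  courses (mean 2.9, dispersion 1.5 — overdispersed so per-patient medians
  of ~2 emerge with a realistic right tail).  Course ages draw from a band
  mixture concentrated at 12–60 months (~90% of records under 60 months);
  medications draw from a mix dominated by amoxicillin, amoxicillin-
  clavulanate and azithromycin; tiers and encounter types from categorical
  mixes.
* **Capture.** Two channels, because the two downstream analyses target
  exactly these mechanisms: (1) per-course prescription/dispensing capture
  failure, with covariate log-ORs applied on the failure logit (including
  a strong "missing same-day encounter" effect — a course handled outside
  the institution leaves neither an encounter row nor an order); and
  (2) whole-patient prescription non-capture, for patients whose primary
  care is elsewhere, which is what creates patient-level false negatives.
* **Lag.** Captured fills appear after a day-level lag (mass 0.98 within
  the 7-day window by default); mass beyond the window produces unmatched
  records even under perfect capture, and
  `expected_unmatched_fraction` gives the closed-form expectation that the
  empirical rates converge to.

The bundled profiles are **calibrated**: `cids_default` reproduces
closed-system-scale match rates (~90.5% of prescriptions, ~92.7% of
dispensings matched) and `noncids_default` open-system-scale rates
(~39.4% / ~64.0%), with calibration constants in
`src/medconcord/data/profiles.yaml`, not code.  Starting values came from
the closed form (rate ≈ capture probability × within-window lag mass) and
were refined against the generator's own empirical output.

What the generator does **not** emulate: real RxNorm/NDC code richness,
seasonality and secular trends in prescribing, dose/days-supply fields,
correlated course timing (refills), between-institution covariate
differences, and informative encounter counts.  Passing tests therefore
demonstrate that the pipeline's logic and statistics are correct under a
known truth — not that any particular real network shares the profiles'
parameters.

## Problem sizes and determinism

Calibration and convergence checks run at 20,000 patients (~58,000
courses), parameter-recovery simulations at 20,000 records × 50
replicates, and oracle-equivalence checks on hundreds of ≤20-record
instances — sizes at which Monte-Carlo error is comfortably inside the
stated tolerances while a full run stays in the minutes range on one CPU.
All randomness flows through a single seeded NumPy generator per cohort:
identical configs give byte-identical tables, and identical inputs give
byte-identical reports.

## Known limitations

* Cross-stream de-duplication interplay: de-duplication is per stream, so
  a narrow-spectrum order can in principle survive while the same day's
  broad-spectrum fill survives on the other side, blocking their match;
  with same-specification matching this only suppresses genuinely
  ambiguous same-day pairs.
* With two institutions per profile, cluster-robust inference is
  anti-conservative; the simulation-validated operating characteristics
  use 20 clusters.
* The published-count arithmetic in the acceptance surface validates the
  summary operations exactly, but odds ratios from undeposited
  patient-level data are validated only by parameter recovery on
  synthetic cohorts, never by comparison to the originals.
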