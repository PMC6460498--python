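# medconcord

Concordance analysis of **EHR prescribing** versus **pharmacy dispensing**
medication records in a common-data-model (CDM) schema.

Observational studies of medication use typically rely on one of two
imperfect sources: prescribing records (provider orders captured in the
electronic health record, coded in RxNorm) or dispensing records (outpatient
pharmacy fills from claims or pharmacy systems, coded in NDC).  Neither is
complete — prescriptions written at outside institutions never reach the
EHR, and fills paid in cash or at out-of-network pharmacies never reach
claims.  `medconcord` quantifies how well the two streams agree, classifies
patient-level exposure misclassification, and models *which* records go
missing.  It was built for pharmacoepidemiologists and data-network analysts
validating CDM extracts, with pediatric oral antibiotics as the motivating
use case.

## What it computes

Given five flat tables (prescribing, dispensing, encounter, diagnosis,
demographic), the pipeline:

1. **Cleans** the medication streams: maps codes to a (spectrum, class,
   name) identity via a lexicon; attaches same-day encounter type and
   infection-diagnosis tier; excludes inpatient/ED records; de-duplicates
   same-day records per patient, keeping the broadest-spectrum agent.
2. **Matches** each prescribing record to a dispensing record of the same
   patient and same medication specification filled within 0–7 days after
   the order (and symmetrically dispensing→prescribing), resolving
   one-to-many candidates by the smallest day gap with one-to-one
   consumption.  Each record gets a binary match flag.
3. **Summarizes agreement**: directional match percentages; per-patient
   record counts binned 0/1/2/3/4+ cross-tabulated between streams; and the
   weighted Cohen's kappa

   κ_w = 1 − Σ wᵢⱼ Oᵢⱼ / Σ wᵢⱼ Eᵢⱼ,  wᵢⱼ = |i−j|/(k−1) (linear; quadratic optional)

   with its asymptotic 95% CI and Landis–Koch label (poor/fair/moderate/
   good/very good).
4. **Classifies exposure** per patient with dispensing as reference:
   TP (≥1 record in both streams), TN (neither), FN (dispensing only),
   FP (prescribing only); sensitivity = TP/(TP+FN), specificity =
   TN/(TN+FP), suppressed for strata whose dispensing capture is unreliable.
5. **Models missingness**: logistic regressions, with institution-clustered
   robust errors, of (a) a dispensing record having no matching prescription
   (race, ethnicity, sex, age band, same-day encounter type, tier, spectrum)
   and (b) a patient being a false negative (sex, race, ethnicity, chronic
   condition, preterm, asthma, encounter-count quartile), plus VIF
   collinearity diagnostics.

Because patient-level network data cannot be shared, the package ships a
**synthetic cohort generator** with institution profiles, two independent
missingness channels (per-course capture failure and whole-patient
prescription non-capture), pharmacy lag distributions, and covariate effects
planted on the capture-failure logit — so every stage is testable against a
known ground truth.

## Worked example

```python
from medconcord import generate_cohort, load_profile, run_pipeline

cfg = load_profile("cids_default", seed=11, n_patients=3000)
tables, truth = generate_cohort(cfg)
report = run_pipeline(tables).strata["cIDS"]
print(report.table1.to_string(index=False))
```

prints

```
                            metric   value                     display
                    total_patients 3000.00
         total_prescribing_records 7716.00
prescribing_per_patient_median_iqr     NaN                     2 (1-4)
             prescribing_matched_n 7021.00
           prescribing_matched_pct   91.00
          total_dispensing_records 7601.00
 dispensing_per_patient_median_iqr     NaN                     2 (1-4)
              dispensing_matched_n 7021.00
            dispensing_matched_pct   92.40
                    weighted_kappa    0.91 0.91 (0.90-0.92), very_good
```

91.0% of prescriptions were filled within 7 days and 92.4% of fills have a
same-specification order preceding them — the signature of a closed
integrated delivery system, where care and pharmacy live in one
organization.  The weighted kappa of 0.91 ("very good") says per-patient
record *counts* agree almost perfectly too.  Running the same pipeline on
the `noncids_default` profile yields ~40%/64% match rates and κ≈0.5: open
systems capture only the fills their data-sharing agreements reach.

The `examples/` directory has one short script per capability
(`match_records.py`, `synthetic_cohort_report.py`,
`exposure_classification.py`, `missingness_model.py`); each prints what it
computes and says what the numbers mean.  A thin CLI wraps the same calls:

```bash
medconcord synth --profile cids_default --seed 1 --n-patients 5000 --out cohort/
medconcord run --input cohort/ --out report/
medconcord match --rx cohort/prescribing.csv --disp cohort/dispensing.csv --out pairs.csv
```

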