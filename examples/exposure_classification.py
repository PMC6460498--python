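"""Sensitivity/specificity of EHR prescribing as an exposure test.

Uses dispensing records as the reference standard for "ever exposed to an
antibiotic" and evaluates how well prescribing records recover it, first on
published patient counts (exact arithmetic), then on a small synthetic
cohort where the truth is known.
"""

import pandas as pd

from medconcord import (classify_patients, generate_cohort, load_profile,
                        summarize)

# --- published-count arithmetic: closed integrated delivery systems ---
# 84,566 patients: 64,187 TP, 17,793 TN, 589 FN, remainder FP
cells = ["TP"] * 64187 + ["TN"] * 17793 + ["FN"] * 589
cells += ["FP"] * (84566 - len(cells))
s = summarize(pd.DataFrame({"patid": range(84566), "cell": cells}))
print("closed-system published counts:")
print(f"  sensitivity {s.sensitivity}%  specificity {s.specificity}%  "
      f"false-negative share {s.cell_percent('FN')}%")
# 99.1% sensitivity: almost every patient with a pharmacy fill also has at
# least one prescription in the EHR.

# --- synthetic cohort: open-system profile, lower prescribing capture ---
cfg = load_profile("noncids_default", seed=5, n_patients=5000)
tables, _ = generate_cohort(cfg)
cls = classify_patients(tables.prescribing, tables.dispensing,
                        tables.demographic)
# specificity is suppressed for open systems: incomplete dispensing capture
# makes "false positives" unverifiable there
s2 = summarize(cls, report_specificity=False)
print("\nsynthetic open-system cohort (n=5,000):")
print(f"  TP {s2.n_tp}  TN {s2.n_tn}  FN {s2.n_fn}  FP {s2.n_fp}")
print(f"  sensitivity {s2.sensitivity}%  specificity not reported")
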