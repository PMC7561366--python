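"""Cohort-level statistics on simulated two-site data.

Simulates the two cohorts at their descriptive-table parameters, compares
them with pooled t-tests (with Cohen's d), and prints the feature-outcome
Pearson correlation table including the subgroup analyses.
"""

import pandas as pd

from crygaze import cape_town_cohort_spec, synth_cohort, tampere_cohort_spec
from crygaze.stats import descriptives, run_correlation_table, summary_t_test

tampere, _ = synth_cohort(tampere_cohort_spec(n=52, seed=1))
cape_town, _ = synth_cohort(cape_town_cohort_spec(n=47, seed=2))
records = pd.concat([tampere, cape_town], ignore_index=True)

print("cohort comparison (pooled t, Cohen's d):")
for var in ("f0_hz", "f0var_hz", "orienting_latency_ms", "dwell_index"):
    res = summary_t_test(descriptives(tampere[var]), descriptives(cape_town[var]))
    print(f"  {var:22s} t({res.df}) = {res.t:6.2f}, "
          f"p = {res.p_two_tailed:.3f}, d = {res.cohen_d:5.2f}")

print("\ncorrelation table (Pearson r, two-tailed p, per-cell n):")
table = run_correlation_table(records)
print(table.to_string(index=False,
                      formatters={"r": "{:6.3f}".format,
                                  "p_two_tailed": "{:5.3f}".format}))
# Each row is one cohort x subgroup x feature x outcome cell; subgroups are
# the Tampere beginning-of-bout recordings and the Cape Town participants
# without prenatal SSRI exposure. No multiple-comparison correction is
# applied (alpha = 0.05).
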