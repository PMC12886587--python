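"""Intrasubject ΔPCC perturbation networks.

The reference network PCC_n is the region x region correlation matrix over
the 13 control subjects. Each perturbation subject is appended one at a time;
ΔPCC = PCC_{n+1} - PCC_n measures how much that single subject bends each
interregional correlation. Entries are zeroed below a per-pair Monte-Carlo
critical value, then averaged across subjects.
"""

import numpy as np

from petnets import DeltaPCCConfig, deltapcc_pipeline, generate_cohort, make_fixture

cohort = generate_cohort(make_fixture("paper-default", seed=0))
result = deltapcc_pipeline(cohort.suv_table, DeltaPCCConfig(seed=0))

labels = list(result.region_labels)
sig = result.significant_average()
print(f"{len(result.per_subject)} perturbation subjects; pooled ΔPCC median "
      f"{np.median(result.pooled_deltas):+.3f} (most values sit near zero)")
print("significant averaged entries (|mean ΔPCC| above per-pair threshold):")
for i, j in zip(*np.where(np.triu(sig, 1))):
    print(f"  {labels[i]:<13} - {labels[j]:<13} {result.averaged[i, j]:+.3f} "
          f"(threshold {result.threshold[i, j]:.3f})")

# Only liver and gallbladder pairs should survive: the liver because uptake
# inhibition makes every perturbation subject an outlier there, the
# gallbladder because its extreme variability perturbs its correlations --
# with the liver's mean |ΔPCC| the larger of the two. No region curation was
# needed: the method is uninformed.
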