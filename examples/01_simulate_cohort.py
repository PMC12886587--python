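"""Generate a synthetic whole-body PET cohort and inspect its static SUVs.

The default cohort mirrors a two-arm tracer study: 13 control subjects and 9
subjects scanned after pharmacological inhibition of hepatic uptake. Curves
span 14-2416 s post-injection and are resampled onto the standard 240-point
grid; static SUV is the mean over the last ten minutes.
"""

import numpy as np

from petnets import generate_cohort, make_fixture

cohort = generate_cohort(make_fixture("paper-default", seed=0))
table = cohort.suv_table

print(f"{table.n_subjects} subjects x {len(table.region_labels)} regions")
ctrl = np.array(table.group_labels) == "control"
print(f"{'region':<14}{'control mean':>14}{'rifampicin mean':>17}{'cohort SD':>11}")
for j, region in enumerate(table.region_labels):
    print(
        f"{region:<14}{table.values[ctrl, j].mean():>14.2f}"
        f"{table.values[~ctrl, j].mean():>17.2f}{table.values[:, j].std():>11.2f}"
    )

# Liver uptake drops sharply in the perturbation arm (inhibited transport),
# the blood-derived regions barely move, and the gallbladder's cohort SD
# dwarfs every other region -- the three contrasts the network methods probe.
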