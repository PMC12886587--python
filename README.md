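# petnets

Correlation-network analysis for whole-body dynamic PET.

Whole-body and total-body PET deliver time-activity curves (TACs) for many
organs at once, which makes it possible to study physiology as a *system*:
instead of comparing each organ's uptake in isolation, one can ask how organs
and subjects co-vary. `petnets` implements three complementary
Pearson-correlation network methods for such cohorts — for example a drug–drug
interaction study in which hepatic transporter (OATP) uptake of a radiotracer
is inhibited in one arm:

1. **d-networks** (dynamic, intersubject, informed). For one region, node *i*
   is subject *i*'s TAC; an edge joins subjects whose curves correlate with
   *r* > 0.65 and *p* < 0.001, then a *k* = 3 nearest-neighbour edge
   reduction keeps, per node, only the *k* strongest edges (ties included).
   Because the Pearson correlation compares curve *shape* (it is invariant to
   affine rescaling), a target organ whose kinetics change under treatment
   segregates the arms, while the blood pool does not — even if blood
   amplitude changes.
2. **s-networks** (static, intersubject, informed). Node *i* is subject *i*'s
   "fingerprint": the vector of static regional SUVs (mean uptake over the
   last ten minutes of the standardised curve). Edges need *r* > 0.65 and
   *p* < 0.05, followed by the same *k* = 3 reduction. Curating out an
   erratically behaving region (the gallbladder) lets the network separate
   the arms into two pure connected components.
3. **ΔPCC networks** (static, intrasubject, uninformed). The region × region
   correlation matrix *PCC*<sub>n</sub> over the *n* control subjects is the
   reference; appending one perturbation subject gives *PCC*<sub>n+1</sub>,
   and Δ*PCC* = *PCC*<sub>n+1</sub> − *PCC*<sub>n</sub> is that subject's
   perturbation network. Significance is calibrated by Monte Carlo: under a
   bivariate-normal null with correlation ρ, the critical value is the
   (1 − α) quantile of |r<sub>n+1</sub> − r<sub>n</sub>|. At *n* = 13 and
   ρ = 0 this gives |Δ*PCC*| > 0.18 at α = 0.05, and the threshold shrinks as
   *n* or |ρ| grows. Per-subject matrices are thresholded, then averaged.

Because clinical scan data of this kind are rarely deposited, the package
ships a synthetic cohort generator (`petnets.cohort`) producing whole-body
TAC cohorts with the same statistical structure — strong hepatic group
contrast, a shape-invariant blood pool, extreme gallbladder variability —
on an irregular sampling grid, standardised by linear interpolation to 240
points over 14–2416 s.

## Worked example

```python
from petnets import (DeltaPCCConfig, PipelineConfig, build_snetwork,
                     connected_components, deltapcc_pipeline,
                     generate_cohort, make_fixture)

cohort = generate_cohort(make_fixture("paper-default", seed=0))

g = build_snetwork(cohort.suv_table,
                   PipelineConfig(excluded_regions=("gallbladder",)))
print([len(c) for c in connected_components(g)])
# [13, 9]   <- one pure component per treatment arm

result = deltapcc_pipeline(cohort.suv_table, DeltaPCCConfig(seed=0))
sig = result.significant_average()
print(sorted({result.region_labels[i] for i in sig.nonzero()[0]}))
# ['aorta', 'aorta wall', 'left kidney', 'liver', 'myocardium',
#  'pancreas', 'right kidney', 'ventricle']
```

The s-network splits the 13 control and 9 perturbation subjects into two
clean components once the gallbladder is excluded. The ΔPCC average flags
only liver-involving pairs (every listed region appears through its pair
*with the liver*; e.g. liver–myocardium mean ΔPCC −0.557 against a per-pair
threshold of 0.041): hepatic uptake inhibition bends every correlation the
liver takes part in, with no region curation required.

The `examples/` directory walks through each capability
(`python examples/04_deltapcc.py` prints the full significant-pair table),
and the same pipelines are scriptable from the shell:

```sh
petnets simulate --preset paper-default --seed 0 --out-dir cohort/
petnets snet cohort/static_suv.csv --groups cohort/groups.json --exclude-region gallbladder
petnets calibrate --n 13 --rho 0.0 --alpha 0.05
```

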