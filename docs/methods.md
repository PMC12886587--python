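# Methods

## Data model and standardisation

Dynamic data are time-activity curves (TACs) in SUV units (activity
normalised to injected dose and body weight, dimensionless), sampled on
whatever irregular frame schedule the scanner produced. Because frame
schedules differ between scans, every curve is standardised by piecewise
**linear interpolation** onto a fixed grid of 240 equally spaced points from
14 s to 2416 s post-injection (~10 s spacing over ~40 min). Linear
interpolation is used because it passes exactly through the measured frames
and does not smooth the data; no extrapolation is performed — scans whose
frames do not cover the full span are rejected rather than padded.

The **static SUV** of a curve is the arithmetic mean of all grid samples in
the last ten minutes (time ≥ t_end − 600 s, inclusive, i.e. 60 samples on
the default grid). Region combinations (e.g. blood pool = aorta + ventricle)
use the unweighted element-wise mean; nothing in the analyses depends on the
weighting, and volume information is not available at this level.

## Correlation and significance

All edges carry the Pearson product-moment correlation *r* (Spearman rank
correlation is available as an option for monotonic-but-nonlinear settings).
Two-sided p-values come from the classical transform
t = r·√((m−2)/(1−r²)) with m−2 degrees of freedom.

Two caveats are deliberate properties of the method rather than oversights:

* For dynamic networks m = 240 interpolated samples, which are strongly
  autocorrelated; the p-values are therefore *nominal*, and in practice the
  r > 0.65 gate is the binding constraint.
* No multiple-testing correction is applied across edges; edge significance
  is a screening device, not a confirmatory test. An optional
  Benjamini–Hochberg mode exists for the ΔPCC pipeline but is off by
  default.

For static networks over 8–9 regions, m is the number of *included* regions
(after any exclusion), so excluding a region changes both r and its p-value.

## Graph construction

From a correlation matrix, edge (i, j) exists iff r > r_min (strict) **and**
p < α. All entities remain as nodes even when isolated. The
**k-nearest-neighbour edge reduction** then keeps an edge iff it ranks within
the top k by weight for *at least one* endpoint, with all edges tied at the
k-th weight retained. Union semantics were chosen because they are the only
reading under which a node can never lose its own strongest edge; an
intersection variant is available. The reduction is idempotent and monotone
in k. Defaults: r_min = 0.65; α = 0.001 (dynamic) or 0.05 (static); k = 3.

Group structure is summarised by the between-group edge fraction and
per-group edge densities, and judged against a label-permutation null
(node labels shuffled, edge set fixed; default 1000 permutations).

## ΔPCC perturbation networks

Let PCC_n be the region × region Pearson matrix over the n reference
(control) subjects' static SUVs. For one perturbation subject, PCC_{n+1} is
the same matrix after appending that subject's row, and
ΔPCC = PCC_{n+1} − PCC_n. The method is *uninformed*: all regions enter, no
curation.

**Significance calibration.** How far one added observation can move a sample
correlation depends on both n and the underlying correlation ρ, so a single
fixed threshold is inappropriate in general. The null is simulated directly:
per replicate, draw n pairs from a bivariate normal with correlation ρ,
compute r_n, append one more pair from the same distribution, compute
r_{n+1}, and record |r_{n+1} − r_n|; the critical value at level α is the
(1 − α) quantile. At n = 13, ρ = 0, α = 0.05 this yields ≈ 0.18, and the
critical value decreases monotonically in both n (the influence of one point
on r scales like 1/n) and |ρ| (a tight elliptical cloud is harder to bend).
The simulation is vectorised and chunked; 100,000 replicates take on the
order of a second.

Two design choices deserve note:

* **Per-pair thresholds by default.** A `ThresholdCurve` is calibrated once
  on a |ρ| grid (0 to 0.95, 20 points) at the reference n, and each region
  pair's critical value is interpolated at its *observed* reference
  correlation, treating the sample PCC_n as a plug-in estimate of ρ. The
  null's |Δ| distribution is symmetric in the sign of ρ, so only |ρ| matters.
  A fixed global threshold (0.17 or 0.18) is available for comparability
  with a flat operating point. The plug-in conditions on the population ρ
  equalling the observed value, not on the sample r_n being exactly that
  value; the conditional variant would require nested simulation and is not
  implemented.
* **Zeroing, not dropping.** When averaging per-subject ΔPCC matrices, each
  matrix first has its sub-threshold entries set to 0; the average then runs
  over *all* perturbation subjects at every element. Subjects without a
  significant change attenuate the group mean instead of being excluded,
  so a minority of non-responding subjects does not erase a group effect but
  does scale it honestly.

Empirical p-values for the optional FDR mode come from per-grid-point null
quantile tables (999 quantiles) stored in the `ThresholdCurve`.

## Synthetic cohort generator

The generator emulates the data a two-arm hepatic-transporter inhibition
study produces, not the physiology itself. Defaults (preset
`paper-default`): 13 control + 9 perturbation subjects, nine regions (left
and right kidneys, liver, aorta, aorta wall, ventricle, myocardium,
gallbladder, pancreas), irregular raw sampling (10 s frames to 170 s, then
120 s frames to 2450 s) covering the standard grid.

Kinetic building blocks, in SUV units:

* **Blood input**: gamma-variate bolus (peak ~11 SUV near 60 s) plus a
  slowly equilibrating tail (~1.2 SUV); aorta and ventricle are scaled copies.
  In the perturbation arm the blood *amplitude* is multiplied by
  `blood_effect` (default 1.15) — tracer not taken up by the liver
  redistributes into blood — while the *shape* is arm-independent, so
  time-course correlations cannot distinguish the arms by blood pool.
* **Liver**: 0.4 × blood + saturating uptake with amplitude 12 SUV
  (τ ≈ 500 s), multiplied by `liver_effect` (default 0.35) in the
  perturbation arm and by a per-subject lognormal transporter-abundance
  factor (σ = 0.05). Scaling the uptake term changes the blood:uptake mixture
  and hence the curve shape, which is what the liver d-network detects.
* **Gallbladder**: 0.2 × blood + a filling ramp with random onset
  (uniform 500–1900 s) and lognormal amplitude (median 7 SUV, CV = 1.5) in
  *both* arms — extreme, treatment-independent inter-subject variability.
* **Kidneys, myocardium, pancreas, aorta wall**: low-amplitude mixtures of
  blood and slow uptake.

Inter-subject noise has four components: a shared per-subject lognormal
scale (σ = 0.15; imperfect dose/weight normalisation, which also induces the
positive interregional correlations a reference network shows), a small
per-region multiplicative term (σ = 0.03), an additive region-independent
background offset (σ = 0.12 SUV; spill-over-like, it shifts static values
but is invisible to time-course correlation), and multiplicative per-frame
measurement noise (2%). Kinetic time constants are jittered per subject
(σ = 0.10 in log). Keeping the dominant static variability additive and
region-iid matters structurally: k-NN reduction disconnects a
near-homogeneous group wherever one similarity axis dominates and has a gap
in its order statistics, whereas exchangeable similarity rankings keep each
arm's 3-NN union graph connected — which is also how the reference study's
control arm behaves.

Presets: `paper-default` as above; `null` sets liver_effect = 1 and
blood_effect = 1 (all group effects off, noise structure untouched);
`strong-effect` (liver_effect = 0.15, blood_effect = 1.3) exaggerates the
contrast and is the fixture guaranteed to yield two-component s-network
separation. Everything is deterministic under the `CohortSpec` seed.

**What the generator does not emulate** — and what passing tests therefore do
not certify about real data: physiologically calibrated pharmacokinetics,
radioactive decay and scanner noise models, attenuation/scatter residuals,
inter-regional spill-over, subject motion, and realistic per-organ SUV
magnitudes (figure-scale placeholders only). Tests on synthetic cohorts
validate the *statistical machinery* — that the pipelines detect the
contrasts they are designed for at the stated error rates — not clinical
effect sizes.

## Problem sizes and numerical choices

Default analysis sizes follow the study design they emulate: 22 subjects,
9 regions, 240 time points. Monte-Carlo calibrations use 100,000 replicates
(200,000 in the acceptance script); permutation diagnostics use 1000
shuffles; the null false-positive check spreads 500 perturbation subjects
over 25 independent reference cohorts so the measured rate is not hostage to
a single reference realisation. Correlations are clipped to [−1, 1] against
floating-point drift; p-value matrices are symmetrised exactly; |r| = 1 maps
to p = 0 rather than a division error; zero-variance inputs raise an
`UndefinedCorrelationError` naming the offending entity instead of returning
a silent 0. The ΔPCC diagonal is never tested (its threshold is set to ∞).

## Known limitations

* The bivariate-normal calibration null is a model choice; heavy-tailed
  regions (the gallbladder) exceed it slightly more often than α, which is
  visible — and intended — as that region lighting up in ΔPCC averages.
* Nominal p-values for dynamic networks (autocorrelated samples), no
  edge-level multiplicity control, and plug-in ρ estimation are inherited
  properties of the method family rather than adjustable knobs.
* ΔPCC matrices compare a perturbation *group* against a reference cohort;
  they are not designed to rank individual perturbation subjects against one
  another.
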