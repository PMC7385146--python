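# Methods

This note documents the models, parameter choices, and numerical conventions
behind `cytoboot`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Synthetic study generator

The generator emulates a two-arm perioperative immune-monitoring design:
patients randomized to a treatment ("MP") or control arm, sampled at a
baseline draw and five post-surgery timepoints (1 h, 6 h, 24 h, 48 h, 2 wk),
with a 26 phenotypic + 11 functional marker panel. Defaults: 30 control vs 28
treatment patients; 1 500–2 500 cells per sample (a range, so the √(N/2)
cluster-count rule is exercised at varying N); eleven cell populations — one
neutrophil, five innate (classical/non-classical monocytes, mDCs, NK cells,
M-MDSCs) and five adaptive (naive/memory CD4 T, CD8 T, B cells, Tregs) —
with mixture fractions loosely matching whole-blood immunology (neutrophils
20 %, CD4 T 28 %, ...).

**Generative model.** Per sample, population counts are multinomial over the
(possibly effect-adjusted, renormalized) mixture fractions; marker values are
independent Gaussians per population *on the arcsinh scale* (the scale on
which the pipeline operates; raw values are recoverable by the inverse
transform). Lineage-defining phenotypic markers sit at a high level (3.8) and
all others at a low level (0.3), with spread 0.35; functional markers sit at
0.8 with spread 0.4. These numbers are stand-ins chosen once for plausible
arcsinh-scale cytometry ranges — the emulated trial is a randomized
experiment, not a generative model, so no distribution could be copied from
it.

Two perturbation types exist. A *surgery response* adds per-population,
per-marker, per-timepoint shifts to **both** arms (defaults: strong early
STAT3/CREB/MAPK activation in monocytes and neutrophils, milder STAT3/STAT5
movement in T cells, decaying to zero by 2 wk). *Arm effects*
(`EffectSpec`) multiply one population's fraction and/or shift its
functional means only in the target arm at listed post-baseline timepoints;
they are the recoverable ground truth.

**What the generator does not model:** marker correlations within a
population, zero inflation, doublets/debris, acquisition drift, barcoding or
spillover artifacts, and patient-level random effects (a patient's samples
are independent draws given the design). Passing tests therefore demonstrate
that the pipeline recovers effects of the planted kind under clean mixture
data — not that it is robust to instrument artifacts or inter-patient
heterogeneity beyond the multinomial/Gaussian noise.

## Features

- Arcsinh cofactor: 5 (the mass-cytometry convention; configurable). A
  `CellTable` carries a scale flag and the transform refuses to run twice —
  double-arcsinh is a classic silent bug.
- Mononuclear population frequencies are percentages of non-neutrophil cells
  (summing to 100 per sample); neutrophils are a percentage of all cells.
- A signaling *response* is the difference of arcsinh-scale medians between a
  post-baseline sample and the same patient's baseline, per population and
  marker ("arcsinh ratio" = difference, never a quotient).
- Empty populations/clusters give missing medians, which propagate as missing
  — never zeros, which would fabricate "no response". The classifier imputes
  missing values with training-half medians inside each CV iteration.

## Bootstrapped metaclustering

- k rule: k = round(√(N/2)) (half away from zero, floor 1), N the sample's
  cell count after neutrophil exclusion. Samples with fewer cells than k fall
  back to k = N with a warning.
- k-means: scikit-learn, k-means++ initialization, 10 restarts, tolerance
  1e-4, Euclidean distance in arcsinh space. Defaults K = 30 metaclusters,
  B = 200 iterations; every per-sample center is one unweighted point in the
  metaclustering.
- Frequencies are normalized by *total* sample events, so excluded
  neutrophils still count in the denominator and per-iteration frequencies
  sum to 100 × (included / total).
- Responses are iteration-matched: a post sample's cluster median is
  compared against the same patient's baseline median under the same
  iteration's cluster definition.
- The classifier feature set per timepoint: frequencies + responses at
  post-baseline timepoints; frequencies + basal medians at baseline (where
  responses are identically zero by construction).

## Classification

Repeated leave-group-out CV: each iteration draws a stratified random half
of the patients per arm for training (the split unit is the patient), fits a
random forest (500 trees by default, √(#features) candidates per split,
unlimited depth, per-iteration derived seed), and scores the held-out half.
Iterations extend until every sample has been scored at least once; a
sample's final value is the median of its held-out scores. AUC is computed
as the Mann–Whitney pairwise statistic (ties count one half); the two-group
p-value is a two-sided Wilcoxon rank-sum test — exact when the pooled count
is ≤ 20 without ties, otherwise the normal approximation with tie and
continuity corrections. A fully tied input returns p = 1.

A calibration note: with ~12 patients per arm and thousands of cluster
features, null-data AUCs spread noticeably wider than the independent-scores
floor (for the Mann–Whitney AUC of independent scores,
sd = √((n₁+n₂+1)/(12·n₁·n₂)) ≈ 0.12 at 12 vs 12), and the rank-sum p-value
on the cross-validated scores rejects more often than its nominal level,
because chance feature–label correlations are shared between training and
test halves and correlate the per-sample scores. The null-calibration test
in the suite quantifies both effects at desk scale. This is a property of
cross-validated scores at small n, not of the implementation; it shrinks at
larger patient counts, and the per-timepoint p-values should be read as
descriptive rankings rather than calibrated error rates at small n.

## Atlas

Cluster coordinates are the first two principal components of the
(iteration · metacluster) × phenotypic-marker matrix of pooled-cell medians,
centered but not scaled (all markers share arcsinh units). Statistics are
raw rank-sum p-values — the reported map is the *best* univariate p per
cluster and sign(r)·(−log₁₀ p) per feature, with sign(r) = +1 when the
feature's mean is higher in the treatment arm and 0 on an exact tie. A
Benjamini–Hochberg layer exists but is off by default: the headline statistic
is deliberately the uncorrected best p, and the maps are read as a screening
visualization, not confirmatory inference. Features missing in more than half
of either arm are excluded from testing. Enrichment of a population among
top-decile best-p clusters is a one-sided hypergeometric test on cell counts;
with many cells it is extremely sensitive, so it is paired with the
population's share in those clusters when interpreted.

## Trajectories

Per-sample vectors of population frequencies + signaling responses are
baseline-subtracted (each patient's baseline maps to the origin), scaled to
unit variance per feature, split into innate (neutrophils included) and
adaptive compartments, and embedded separately into one Isomap dimension
(k-NN graph → shortest-path geodesics → MDS eigen-embedding, dense solver).

Unit-variance scaling is a deliberate design choice: frequencies live in
percent units (noise ~1 percentage point) while responses live in arcsinh
units (noise ~0.05), so without scaling both axes simply track frequency
noise and no signaling effect, however large, can move an axis. Scaling can
be disabled (`standardize=False`).

Default n_neighbors = 10; studies whose (arm, timepoint) groups are small and
widely separated may need k at least the group size, since a planted gap
larger than the within-group spread otherwise disconnects the neighborhood
graph (the error names the component sizes). Axes are sign-ambiguous
eigenvectors; the convention is that the group-median coordinate at the
first post-baseline timepoint is ≥ the baseline median. The least-squares
linear map from feature space to each axis is an affine extension used to
interpolate continuous trajectories between consecutive timepoints for
animation; it is an interpretation of the "linear transformation after
dimension reduction" step, not an out-of-sample Isomap (Nyström) embedding.

A note on "adaptive-only" perturbations: population frequencies are closed
(they sum to 100), so a frequency change in an adaptive population
necessarily moves innate frequencies through renormalization. A
compartment-local perturbation must therefore be signaling-only; and because
each compartment axis is one dimension among ~60 unit-variance features, a
shift is only recoverable on the axis if it spans enough correlated features
(e.g., a JAK/STAT motif across all adaptive subsets) to dominate the
leading eigen-direction.

## Problem sizes in the test suite

The simulation-based tests run the full pipeline at reduced sizes chosen as
this package's desk-scale study conditions: B = 20, K = 10; 12 vs 12
patients × 1 000 cells for null calibration (50 studies); 10 vs 10 patients ×
2 000 cells with a planted one-population effect (frequency × 0.5, +1.0
arcsinh pSTAT3 shift) for effect recovery and atlas localization (20
studies); 30–50 CV iterations with 100-tree forests for the classifier
inside these loops. The demo runs 6 + 6 patients over four timepoints. Full
printed defaults (B = 200, K = 30, 200 iterations, 500 trees) remain the
library defaults.

## Known limitations

- FCS support is a minimal list-mode float reader/writer (3.0/3.1); integer
  FCS data and escaped delimiters are not handled.
- Population labels stand in for manual gating everywhere; no gating
  hierarchy is implemented.
- The LOGO-CV rank-sum p-value treats per-sample median probabilities as
  exchangeable scores; correlations induced by shared training sets make it
  mildly anti-conservative at small n (see the calibration note above).
- Isomap axes from separate compartments have independent, data-driven
  scales; cross-axis ratios are meaningful only because both compartments'
  features are variance-normalized.
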