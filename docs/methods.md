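# Methods

This note records the models implemented in `hypoflow`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data do and do not establish about behaviour on real data.

## Quadrant model and gating

Events carry five strictly positive channels (FSC, SSC, FL1, FL2, FL3).
Classification applies fixed precedence: PI positivity (FL3 above the gate)
labels an event dead (Q1) regardless of every other channel — dead cells
cannot maintain membrane potential, so a bright TMRE value on a PI-positive
event is treated as noise, not as Q2. Among PI-negative events, NAO-dim
(FL1 at or below the gate) marks live apoptotic cells with oxidized
cardiolipin (Q3) before TMRE is consulted; the remaining events split on
TMRE into high-MMP (Q2) and collapsed-MMP (Q4). Every event receives
exactly one label, so the four fractions always sum to 1 and the cytotoxic
endpoint Fa = Q1 + Q3 is well defined.

MFI is the arithmetic mean on the linear intensity scale, the conventional
cytometry reading; a geometric-mean option exists because log-acquired data
are sometimes summarised that way. The MFI of an empty quadrant is NaN,
never zero. No scatter pre-gate is applied by default (scatter is only
descriptive in this assay); a rectangular FSC/SSC pre-gate is available.

`auto_gates` places each fluorescence threshold at the minimum-density
valley between the two largest modes of the pooled log10-intensity KDE
(512-point grid), falling back to the midpoint of the log-range with a
warning when the distribution is unimodal. Real experiments of this kind
gate manually; automatic gates are reproducible only relative to the
supplied control samples, which is why quadrant fractions from published
figures cannot be regenerated exactly.

## Median-effect dose–response

The quantal median-effect model log10(Fa/Fu) = m·log10 D − m·log10 Dm is
fit by unweighted OLS on the log–logit scale, the classic procedure for
this model. Base-10 logarithms are used throughout; the base cancels in
every derived quantity except the reported intercept. Saturated points
(fa outside (ε, 1−ε), ε = 0.005 by default) are **excluded and recorded**,
not clamped — clamping would drag the slope toward zero. At least two
usable points at distinct doses are required; a non-positive fitted slope
flags the fit as non-monotone rather than failing, and Dm is undefined
(NaN) in that case. EC50 ≡ Dm exactly, and `effect_at_dose` /
`dose_for_effect` are algebraic inverses (round-trip accurate to 1e-12).

Combination analysis presupposes the fixed-ratio convention: the
combination series is fitted on **total** dose at a declared a:b ratio
(proportions summing to 1, never inferred from data). At each effect level
the total combination dose splits by the ratio into component doses, giving
CI(i) = Dac/Das + Dbc/Dbs and DRI = Das/Dac (resp. Dbs/Dbc), so
CI = 1/DRIa + 1/DRIb holds identically. The additivity band is
[0.9, 1.1] by default and configurable; published work often calls CI
"well below 1" synergistic without giving a band.

`bootstrap_fit` resamples the per-dose affected fraction as
Binomial(n_events, fa)/n_events and refits, which propagates exactly the
event-counting noise the quantification step produces; when event counts
are unknown it degrades to case-resampling over dose points with a warning.

## Signal-to-noise ranking and enrichment

S2N = (x̄1 − x̄2)/(s1 + s2) per gene, with each group SD floored at
max(0.2·|mean|, 0.2). The floor follows the GSEA default and is essential
at n = 3 per group, where a lucky near-zero SD otherwise dominates the
ranking. An audit mode computes the denominator as (s1 − s2) verbatim; it
exists only to reproduce a printed formula — a difference of SDs can be
zero or negative and is not a dispersion measure — and is not used
anywhere in the pipeline. Ties in the ranking break lexicographically by
gene id so runs are bit-reproducible.

The expression filter keeps exactly the genes with at least `min_count`
(default 10) counts in **every** sample and is defined only for counts
data. Log-fold-changes in counts mode first scale columns to a common
library size (the mean total count) and then compare means with a
pseudocount; normalization is configurable because upstream pipelines
differ on CPM vs raw input.

The enrichment score is the signed maximum deviation of the weighted KS
running sum (hits add |score|^p normalised over hits, default p = 1;
misses subtract 1/(N − N_hits)). When the maximum and minimum deviations
tie in magnitude (within 1e-12) the positive one is reported. The
permutation engine evaluates the running sum only at positions adjacent to
hits — the walk is piecewise linear between hits, so these 2k candidates
contain the extrema — which makes 500 sets × 1000 permutations a
seconds-scale computation; the full O(N) walk is retained in
`enrichment_score` and the two paths are cross-checked in the test suite
against a brute-force oracle.

Significance uses gene-set permutation (random same-size sets), the
appropriate scheme at 3 samples per group where phenotype permutation has
only 10 distinct splits; phenotype mode exists for larger designs and
falls back (with a warning) below 7 samples per group. The nominal p-value
is add-one and normalised within the same-sign permutation subset,
p = (1 + #{|ES_perm| ≥ |ES_obs|, same sign}) / (1 + #{same sign}): dividing
by all permutations instead would cap the null p near the sign fraction
(~0.5) and destroy null uniformity. NES divides ES_obs by the mean |ES|
of matching-sign permutations. FDR is Benjamini–Hochberg across sets on
the nominal p-values — simpler and distribution-free compared with the
NES-histogram FDR of the original GSEA software, and documented as a
deliberate simplification.

## Cohort clustering and contrasts

Samples are clustered on their signature-restricted expression vectors
with Euclidean distance and complete linkage; the tree is cut into k
clusters and clusters are renumbered by decreasing size, so "cluster 1" is
always the largest. Row scaling defaults to none (cluster on the values as
provided); a per-gene z-score mode is available because row-scaled heatmap
displays are common and the two conventions can cut differently — analyses
should report which mode they used. Signature genes absent from a cohort
are dropped with a logged list, never imputed.

Two merge helpers condense a k-cut to the biologically meaningful
two-group view: `auto_merge_cp` joins all clusters whose plurality
clinical label is CP (the "Cluster_1+3" construction), and
`merge_by_plurality` joins clusters sharing any plurality label, which is
robust to the cut splitting either profile group.

The contingency analysis is a Pearson chi-square without continuity
correction on the cluster × clinical-label table, with both composition
views (% of cluster from each class; % of class in each cluster). When any
expected cell falls below 1 the statistic is flagged unreliable and a
seeded Monte-Carlo permutation p-value (labels shuffled, add-one) is
offered.

Contrast correlation is Spearman's rho with average ranks, a Fisher-z 95%
interval (SE = 1/√(n−3)) and a two-sided t-approximation p-value (df =
n−2); vectors are aligned on shared gene ids and genes missing or NaN in
either are dropped (n ≥ 4 required, constant vectors rejected).

## Synthetic data: what it emulates and what it does not

**Flow events.** Four log-normal populations (one per quadrant) on a
four-decade intensity scale, with per-channel median locations and CVs
(log-scale sigma = √ln(1+cv²)); defaults use CV 0.4 and locations that
separate populations by well over the decision boundaries, so
classification error is negligible and quadrant-fraction estimates are
binomial-limited (~1/√n). The planted affected fraction composes an
environment baseline with the drug's median-effect curve as
fa = baseline + (1−baseline)·Fa_drug; published methods do not state a
composition rule, so a "rescue" alternative fa = baseline·(1 − R(D)) is
also provided (R a median-effect-shaped rescue fraction) and neither is
asserted as *the* rule used in any particular study. Defaults: 20,000
events per sample (the acquisition depth of the assay emulated), slope 2,
Dm 10 dose units. Per-dose seeds derive from (master seed, dose index), so
extending a dose series never perturbs existing samples. Not modelled:
spectral overlap/compensation, doublets, acquisition drift — passing tests
here say nothing about robustness to those artefacts.

**RNA-seq counts.** Gamma-Poisson (negative binomial, var = μ + φμ²)
counts over log-normal baseline abundances (ln-mean 4, ln-SD 1.5 — median
~55 counts), 3 vs 3 design, dispersion 0.05, 5% DE genes at |log2FC| = 2
split symmetrically between the groups, log-normal library-size factors
(SD 0.1). This reproduces the mean–variance behaviour bulk RNA-seq
pipelines assume but not gene–gene correlation, GC/length bias, or outlier
samples.

**Patient cohort.** 62 CP / 17 AP / 32 BC patients over a 25-gene panel;
CP columns follow a per-gene baseline (log2 scale, mean 7, SD 1), BC
columns add a per-gene class effect (SD 1.5 log2 units), and each AP
patient is BC-like with probability 0.46 — a two-component mixture rather
than an intermediate mean, because the clinical category empirically
splits between the two metabolic groups. Unit Gaussian noise by default.
The environment contrast is built by a Gaussian copula against the class
effect: normal scores of the class-effect ranks are mixed with orthogonal
noise at Pearson c = 2·sin(π·ρ_target/6), the inverse of the
bivariate-normal relation ρ_S = (6/π)·asin(c/2), so the pair's population
Spearman correlation equals the target (−0.41 by default). Because the
planted profile origin is binary (CP-like vs BC-like), recovery is
assessed on the k=3 cut **after** plurality merging — a raw three-way
partition necessarily splits one profile group and cannot score a high
Rand index against a binary truth.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the sizes the
analyses describe (20,000 events/dose, 6-dose series, 20-seed recovery
experiments, 2,000-gene count matrices, 500 null sets × 1000 permutations,
113-patient cohorts); the whole suite completes in under a minute on one
CPU, the acceptance script in seconds. Every random draw flows from an
explicit integer seed (`numpy.random.default_rng`); derived seeds come
from `SeedSequence([master, index])` and stay below 2³¹. Identical
configs and seeds reproduce all outputs bit-identically, including file
artifacts of the config-driven pipeline runner.

## Known limitations

- Quadrant gates are data-derived, so absolute fractions from manually
  gated published figures are not recoverable; only relative behaviour is.
- The FDR reported by the enrichment stage is BH across sets, not the
  NES-pooled FDR of the original GSEA implementation; q-values are not
  comparable digit-for-digit with GSEA desktop output.
- The median-effect fit is unweighted; points near fa = 0.5 and points
  near the exclusion threshold carry equal weight.
- The FCS reader is deliberately minimal (list mode, uniform float or
  16/32-bit integer data); it does not implement the full keyword surface
  of the FCS standard, compensation matrices, or multi-dataset files.
- The cohort generator plants a single signature direction; it cannot
  express partially overlapping or anti-correlated sub-signatures.
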