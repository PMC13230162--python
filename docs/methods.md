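# Methods

This note documents the statistical procedures the package implements, the
model behind the synthetic cohort generator, the numerical conventions, and
the limits of what the test suite demonstrates.

## The analysis chain

The package targets a common design in livestock metagenomics: a large
shotgun-sequenced cohort (here, commercial boars of three breeds —
Duroc, Landrace, Large White — housed on three farms run by two
companies) in which group sizes are highly imbalanced (e.g. 498 animals of
one breed next to 85 of another on the same farm) and several factors
(breed, farm, company, age stage, sampling batch) are partially entangled.
The chain is:

1. **Table construction.** Species abundances arrive on the TPM scale
   (each sample's values sum to 10⁶; relative abundance = TPM/10⁶) with a
   companion reads-per-base matrix. Effective fold coverage is
   reads-per-base × average read length (151 bp default). A species is
   retained in a sample only when its coverage strictly exceeds 1×; gated
   rows are re-closed to 10⁶. Upstream read-level filters (alignment
   fraction, identity) are treated as provenance of the input tables, not
   recomputed — no read data exists at this layer.
2. **Diversity.** Observed richness (taxa with abundance > 0), Shannon
   (−Σ p ln p, natural log) and Simpson (1 − Σ p²) per sample; Bray–Curtis
   dissimilarity Σ|xᵢ−xⱼ|/Σ(xᵢ+xⱼ) between samples; classical-scaling PCoA.
   Group comparisons use the Wilcoxon rank-sum test with
   Benjamini–Hochberg adjustment within each index family, plus a
   Kruskal–Wallis omnibus for three or more groups.
3. **Variance partitioning.** Multi-term PERMANOVA on the Bray–Curtis
   matrix (details below), fitted per farm (breed + age_stage + batch) and
   per age stage (farm + breed + batch), with levels of the primary factor
   below a minimum group size (default 10) excluded before fitting.
4. **Bootstrap robustness.** Repeated equal-size subsampling without
   replacement down to the smallest group, re-testing each balanced
   subsample, and reporting the fraction of iterations significant at
   p < 0.05.
5. **Shared-taxa sets.** Presence for set analysis uses the relative-
   abundance rule (> 10⁻⁵) on the coverage-gated table, then an inclusive
   ≥ 10% prevalence cut within each group; intersections are reported in
   the exclusive (UpSet) convention alongside inclusive pairwise overlaps.
6. **Enrichment.** Per-taxon linear models of log relative abundance with
   covariates and a cross-comparison consistency classifier (below).

## PERMANOVA

Let D be the n×n dissimilarity matrix, A = −½ D∘D, and G = JAJ with
J = I − 11ᵀ/n (Gower centering). trace(G) is the total sum of squares.
Each categorical term is dummy-coded (first level reference); for term k
in a sequential (by-terms) fit, the term sum of squares is
trace((H_k − H_{k−1})G), where H_k projects onto the column space of the
intercept plus the first k blocks (orthonormal bases are rank-revealing,
so aliased columns contribute no degrees of freedom). Marginal sums of
squares are SS(full) − SS(full minus term). Pseudo-F is
(SS_t/df_t)/(SS_res/df_res); significance comes from free permutation of
sample labels, implemented by conjugating G with the permutation, with
p = (1 + #{F* ≥ F})/(1 + N) so p is never zero. Both modes are reported
because sequential and marginal R² differ for unbalanced data and both
conventions are in active use; sequential R² values add exactly to 1 with
the residual.

Correctness anchors: on Euclidean distances of a one-dimensional response
the sequential decomposition equals classical type-I ANOVA (checked to
1e-8 against statsmodels); the full table matches vegan's `adonis2` in
both modes on a fixed cohort (checked through Rscript); permutation
p-values match exhaustive enumeration on six-sample two-group instances.

Small-group exclusion in stratified fits applies to the primary (first)
term only. The motivating case is a breed represented by very few animals
in one farm; extending the rule to nuisance terms such as batch would
silently discard large parts of a stratum, so nuisance terms that collapse
to one level are instead dropped from that stratum's formula and recorded.

## Bootstrap

Alpha-diversity runs operate within a stratum (farm): every breed is
subsampled, without replacement, to the smallest breed's size; the three
indices are per-sample quantities and are computed once, so an iteration
only re-draws indices and re-runs the omnibus test (Kruskal–Wallis for
three groups, rank-sum for two; an all-tied sample yields p = 1). Beta
runs subsample every breed-within-farm cell to the globally smallest cell,
recompute Bray–Curtis on the balanced subsample and run a one-term
PERMANOVA on breed. Each iteration's design is asserted balanced. The
summary reports the stability fraction (share of iterations with
p < 0.05), the median p and a 95% p-interval; the conventional
declare-stable cutoff of 0.95 on the fraction is a reporting default, not
a hard-coded decision.

A caution encoded in the test suite: iterations resample one finite
cohort, so per-iteration p-values are strongly dependent. A single null
cohort's stability fraction is not guaranteed near 0.05 — only its
expectation over cohorts is — so calibration checks average the fraction
over independent null cohorts.

## Enrichment models and the consistency rule

Taxa detected in fewer than 5% of samples or with mean relative abundance
below 10⁻⁵ are removed (both boundaries inclusive on the keep side). The
response is ln(relative abundance + pseudocount) with the pseudocount set
per taxon to half its smallest nonzero relative abundance (recorded for
audit). For a three-level primary factor (breed, or age stage), the three
pairwise models restrict to the two levels involved and regress the
response on a contrast-level indicator plus dummy-coded covariates
(company, farm, batch for breed models; company, farm, breed, batch for
age models). Covariate levels absent within the pair drop out; covariate
columns collinear with the rest of the design are pruned by a greedy
rank-preserving sweep that never removes the intercept or the primary
indicator, and the pruning is recorded. The fit is a mass-univariate OLS
(one shared design, all taxa solved at once; verified against per-taxon
statsmodels fits), with a two-sided t-test on the primary coefficient.
Zero-variance responses are flagged degenerate with coefficient 0 and
p = 1.

BH q-values are computed within each pairwise model across taxa — the
family is one model, so "q < 0.05 in both models" is meaningful. A taxon
is labelled enriched in level L only when both models involving L favour
L in sign (positive when L is the contrast, negative when L is the
reference) and both have q strictly below the threshold; sign concordance
makes labels mutually exclusive, and relabelling the reference flips
coefficients but never labels.

Because the models are TSS + log (MaAsLin2's default-equivalent
preprocessing), strong planted effects on high-abundance taxa displace the
rest of the composition and attenuate coefficients; this is inherent to
compositional data, not a defect of the solver. The planted-recovery
benchmark therefore plants on mid-high-baseline taxa (abundant enough to
sit clear of the pseudocount floor, small enough that closure effects are
negligible) — the regime in which a practitioner would call an effect
cleanly identifiable. Compositional log-ratio transforms are an explicit
non-goal.

## The synthetic cohort generator

The generator exists so every stage is testable without the deposited
data. Per sample, log taxon intensity = per-taxon baseline + sparse
additive shifts for the sample's breed, farm, age stage and batch +
N(0, dispersion) noise; intensities are exponentiated and closed to 10⁶.
Reads-per-base = depth_factor × relative abundance × a per-sample
lognormal jitter, so effective coverage straddles the 1× gate (at the
default depth_factor 5 and ~300 taxa, a typical taxon sits a few fold
above 1× and rare taxa fall below). Randomness comes from one seed
sequence spawned into per-sample substreams, so a cohort is reproduced bit
for bit regardless of iteration order.

Defaults and why:

- **Design**: the nine breed-within-station groups with the study's sizes
  (34/113/338, 8/108/301, 498/166/85; total 1,651), ages uniform on
  257–1,906 days, four sampling batches per farm (a batch count the
  source does not state; chosen as a realistic nuisance granularity).
  `study_design(scale=...)` shrinks all groups proportionally (minimum 2)
  for desk-scale runs.
- **Age stages**: young ≤ 365 d (12 months), mid 366–1095 d, aged
  > 1095 d. A day/month convention is not stated at the source; whole-year
  boundaries are used.
- **Community**: per-taxon baselines N(0, 2) on the log scale give the
  heavy-tailed rank-abundance curve typical of gut metagenomes; taxa are
  assigned to seven phyla with weights that make Firmicutes and
  Bacteroidota dominate, as in commercial pig cohorts. Default 300 taxa
  (530 in the recovery benchmark) — far below the ~3,000 species of a
  real cohort, chosen for tractable repeated simulation.
- **Effects**: `study_effect_model` plants disjoint taxon blocks per
  breed/farm/stage/batch level (shifts 1.2/1.2/0.9/0.4 on the log scale,
  dispersion 1.5). These constants were fixed once so that, at the
  study's group sizes, breed explains a low single-digit percentage of
  Bray–Curtis variance with farm comparable and batch smaller — the
  qualitative regime the cohort's analyses operate in.
- **dispersion ≥ 0** is accepted; exactly 0 produces the degenerate
  identical-composition cohort used as a closed-form test case.

The model is log-normal with additive effects because the enrichment
models are linear on log abundances; Dirichlet-multinomial sampling,
zero-inflation, read-level simulation and phylogenetic correlation among
taxa are deliberately absent. Consequently, passing tests demonstrate
correctness of the inference machinery under the stated model — they do
not certify behaviour under real-data pathologies such as structural
zeros, overdispersed counts or taxon covariance.

## Numerical conventions

- Presence thresholds are strict (> 1× coverage, > 10⁻⁵ relative
  abundance); prevalence cuts and the enrichment mean-abundance floor are
  inclusive (≥), with a 1−10⁻¹² relative guard on the mean so summation
  rounding cannot flip the boundary.
- PCoA uses no negative-eigenvalue correction; proportions explained are
  over the positive spectrum, axis signs are fixed by making the
  largest-magnitude loading positive, and requesting more axes than
  positive eigenvalues returns fewer axes with a warning flag.
- Rank-sum tests use the exact null for small untied samples and the
  normal approximation with tie correction otherwise (scipy's policy);
  an all-identical pooled sample short-circuits to p = 1.
- Permutation p-values use the (1 + count)/(1 + N) estimator; F
  comparisons tolerate 10⁻¹² to count ties in degenerate cases.
- Scaled-down problem sizes in tests and the acceptance script (tens of
  samples per group, 40–530 taxa, 99–999 permutations, 200 bootstrap
  iterations) were chosen so repeated Monte-Carlo checks stay cheap while
  binomial tolerances (±3 percentage points at 200 replicates) remain
  meaningful.

## Known limitations

- Sequential R² is order-dependent by construction; the term order is the
  caller's statement of the model, taken verbatim.
- Free permutation is the only scheme; restricted/blocked permutation and
  dispersion (PERMDISP) tests are out of scope.
- Enrichment uses fixed effects only; random-effect structures (e.g.
  repeated measures within batch) are not supported.
- Continuous age cannot enter the distance models; age is always the
  three-level stage factor.
- The consistency classifier requires exactly three primary levels, as in
  the three-breed / three-stage design it implements.
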