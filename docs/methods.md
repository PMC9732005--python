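# Methods

## The integration model

`tdfuse` treats each expression study as an exchangeable view of a
shared gene space. A study is compressed by its own SVD (matrix layout)
or truncated HOSVD (tensor layout) to a genes × L reduced profile
x_{iℓk} = λ_ℓ u_{ℓi}; only these profiles — never the samples — enter
the integration. The stack of K profiles over the common gene universe
is a third-order tensor decomposed by classical truncated HOSVD: each
mode's factor matrix holds the leading left singular vectors of that
mode's unfolding, and the core is the tensor contracted with the
transposed factors. We deliberately use the one-pass HOSVD rather than
HOOI: it is deterministic, exact at full ranks, and the downstream
statistics only need the leading factors of each unfolding.

Assumptions worth making explicit:

- **Shared program, unmatched everything else.** The model assumes the
  biological signal of interest appears as correlated gene-side
  structure across studies. Study-specific structure (batch effects,
  private signals) ends up in factors that no cross-study screen will
  select; it is not removed.
- **Gaussian gene-factor null.** Gene selection assumes the entries of
  a gene factor are approximately normal over genes under the null.
  Orthonormal factors of high-dimensional noise satisfy this well; the
  χ² tail is then slightly conservative (see the null-calibration
  numbers).
- **Sign convention, not sign information.** Singular vectors are
  defined up to ±. Within a study the largest-magnitude entry of each
  gene factor is made positive; across studies each factor is flipped
  to correlate positively with the reference study. Because the
  reference itself is first put in the canonical convention, the whole
  pipeline is exactly invariant to arbitrary sign flips applied before
  alignment — flips are exact negations in floating point, so outputs
  are bit-identical. Near-zero alignment correlations (|r| < 1e-8) keep
  the within-study convention and log a warning.

## Normalization and gene universes

Every sample is normalized over genes to zero mean and Σx² = N on the
study's **native** gene set, then the reduced profiles are zero-filled
onto the universe (default: the largest study's gene list; union
available). Padding after normalization means padded rows carry no
signal, and the moment conditions continue to hold on native rows. We
do not re-normalize after padding — the conditions cannot hold over the
padded length, and re-normalizing would leak universe composition into
the values. Zero-variance genes are retained (they contribute zero
loadings); a zero-variance *sample* is an error naming the sample.
Gene identifiers are opaque strings matched exactly; namespace mapping
is the caller's job.

## Factor choice (Ω) and gene selection

Informative gene-mode factors are ranked by Σ G², summed over non-gene
core indices, optionally restricted to fixed values of the other modes
(used by the single-cell path: fix ℓ₃ to the group-associated
measurement factor, take the top ℓ₁).

The full pipeline (`run_full_pipeline`) instead chooses Ω as the set of
factors whose sample projections pass the association screen against
the studies' own labels — the same logic by which the method's analyses
settle on their factor sets in practice: a factor is worth testing genes
against exactly when its coordinates track some study's classification.
With no labels (or nothing significant) it falls back to the top-n core
weight. This matters statistically: adding label-irrelevant factors to
Ω inflates the χ² degrees of freedom and dilutes the statistic.

σ_{ℓ₁} is the sample standard deviation of u_{ℓ₁i} over all universe
genes; an `exclude` mask allows dropping zero-padded genes from the
estimate. Selection thresholds are strict inequalities (adjusted
P < 0.01 for genes, < 0.05 for factor screens). BH adjustment is the
exact step-up: sorted p·n/rank, cumulative minimum from the largest,
capped at 1.

The association screen is one-way ANOVA (the categorical linear model)
of each factor coordinate on class. BH is applied per study for
per-study tables, and **jointly across all factor × study P-values**
for the run-level screen that gates Ω — the joint screen is what
controls the whole run's error at the nominal level; per-study
screening compounds to 1−0.95^K under the global null.

## Drug ranking

A drug × dose × replicate tensor is normalized, padded to the universe,
and projected onto the leading gene factors (default 4). Each projected
slice is decomposed with full square factors (drug factors are
drugs × drugs), and drug d scores Σ_{t≤T} ũ²_{td} with T = 5. The score
is a relative-energy measure: a drug whose response lives in the
leading singular vectors of the projected slice scores near 1, a drug
whose variation is spread over the noise components scores near
T/(number of drugs-mode components). It discriminates best when the
responsive drugs span several strong components — i.e. when the panel's
responses are diverse, as in real compound screens.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given their seed; tests and the
acceptance script derive every seed from one master seed.

**Unmatched studies** (`generate_unmatched_studies`, defaults
N = 2000 genes, sample sizes (9, 23, 8), 100 planted genes, effect
2 SD, unit Gaussian background): each study has its own balanced class
assignment; a sample of class c shifts planted gene i by
sign_i · effect · w_c with class weights evenly spaced on [−1, +1], so
extreme classes differ by 2·effect gene-level SDs; a per-study scale in
[0.75, 1.25] jitters amplitude. The sample sizes mirror the small
case/control studies this method targets.

**Drug tensor** (`generate_drug_tensor`, defaults 94 drugs × 4 doses ×
3 replicates, top-dose response 3 SD): effective drugs respond along
the planted program with Hill-type dose curves, normalized to full
response at the top tested dose, with EC50s stratified across the dose
range (early/mid/late responders) and slopes in [2, 5]. The
stratification emulates the potency spread of a real panel; it is also
what makes the effective drugs' responses span several singular
components, which the top-T score needs. The 3 SD top-dose response
reflects the strong signatures active compounds show at maximal dose;
note that per-sample normalization caps the realized amplitude (a
sample's total variance is fixed), so responses saturate rather than
grow without bound.

**Single-cell collection** (`generate_scrna_collection`, defaults
2000 genes, 6 measurements × 500 cells, 4 groups, effect 1.0, dropout
0.5, donor variability 0.05): counts are Poisson draws from per-gene
rates, Bernoulli-thinned. The planted disease program is built from
up/down **pairs** of genes with equal baseline rates: disease
multiplies the up member's rate by e^{effect} and the down member's by
e^{−effect} (reversed in controls). Pairing makes every symmetric
functional of the rate vector — library size, concentration — identical
in distribution across groups, so the program direction is the *only*
systematic group difference; groups also cycle with alternating disease
status, keeping the design balanced (an unbalanced design provably
mixes the program into the baseline factor of the joint decomposition).
Per-measurement log-normal donor noise supplies a realistic
within-group variance floor for the F-tests.

What passing these benchmarks does **not** show: the generators have no
batch effects, no cell-type heterogeneity, no mean–variance trends, and
planted programs orthogonal by construction to nuisance directions.
Real data will put more energy into label-irrelevant factors and make Ω
selection harder; the benchmarks validate the machinery and its
calibration, not robustness to confounding.

## Numerical choices and problem sizes

- SVDs via LAPACK (`numpy.linalg.svd`), economy except where square
  drug-mode factors are required; no randomized methods, everything
  deterministic.
- Gene-mode rank of the integration HOSVD is L·K — the exact nonzero
  spectrum of the mode-1 unfolding; nothing is truncated away.
- Tensor-study reduction enumerates columns row-major over the
  mode-component tuple (ℓ₁, …, ℓ_S).
- Ties in factor ranking break by factor index; ties in gene-table
  ordering break by gene id; both orderings are deterministic.
- The test suite and acceptance script run at desk scale: studies of
  500–2000 genes, single-cell collections of 6 × 500 cells,
  10-drug panels; each full pipeline run takes well under a second and
  the whole acceptance script a few seconds. These sizes were chosen so
  the per-gene χ² statistics have clear margins (the statistic scales
  with N divided by the planted-set size) while keeping everything
  quick to rerun.

## Known limitations

- The single-cell gene-level selection has limited power at 6
  measurements (the measurement screen's F-test has only 2 residual
  degrees of freedom with 4 groups); the screen reliably finds the
  disease factor, but gene-level sensitivity at this scale is modest.
- The null association screen is calibrated, not conservative: under a
  global null the probability that *some* factor passes the joint
  BH screen equals the nominal 5% (Simes identity), so about one
  pure-noise run in twenty reports a spurious factor.
- Exact-string gene matching means annotation-release differences
  between studies silently reduce the shared universe.
- CMF and GFA, externally maintained comparison methods, are not
  re-implemented; the included baselines are concatenation-SVD and
  per-study PCA overlap.
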