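# Methods

## The categorical shrunken-centroid model

Let `x_ij` be the genotype of SNP `i` in sample `j`, taking values in the
category set `{AA, Aa, aa, missing}` (or `{AA, Aa, aa}`; see *Missing
handling*). With `K` classes, `C_k` the index set of the `n_k` samples of
class `k`, and `e(·)` the one-hot indicator over the category set:

* **Centroids.** The class centroid of SNP `i` is its within-class mode
  (most frequent category); the operative centroid for distances and
  classification is the genotype distribution vector `f_ik` (within-class
  category frequencies). `f_i` denotes the pooled distribution over all
  samples.
* **Dispersion.** `s_i² = (1/(n−K)) Σ_k Σ_{j∈C_k} ‖e(x_ij) − f_ik‖₂²`,
  the pooled within-class scatter of one-hot indicators around the class
  distribution — the categorical analogue of a pooled within-class
  standard deviation. We compute it through the identity
  `Σ_{j∈C_k} ‖e(x_ij) − f_ik‖² = n_k (1 − ‖f_ik‖²)`, which the test suite
  verifies against direct loop summation.
* **Standardized distance.** `d_ik = ‖f_ik − f_i‖₂ / (m_k (s_i + s₀))`
  with `m_k = sqrt(1/n_k − 1/n)` by default (`m_rule="add"` gives the
  `sqrt(1/n_k + 1/n)` convention, which also appears in the
  shrunken-centroid literature).
* **Shrinkage.** Soft thresholding `d'_ik = max(d_ik − Δ, 0)`; the class
  distribution is pulled toward the pooled one proportionally,
  `f'_ik = f_i + (f_ik − f_i)·d'_ik/d_ik`, which is a convex combination
  and therefore always a valid probability vector. A SNP is selected when
  `max_k d'_ik > 0`; the selected set is non-increasing in Δ.
* **Classification.** `δ_k(t) = Σ_i ‖e(t_i) − f'_ik‖₂²/(s_i + s₀)² −
  2 log π_k`, minimized over classes. The squared `(s_i+s₀)` denominator
  is the direct analogue of the classical discriminant score; priors `π_k`
  default to empirical class proportions, with a uniform option. Score
  ties go to the class with the larger prior, then the lower class index.
  An alternative mode (`use_shrunken=False`) classifies with the
  *unshrunken* `f_ik` restricted to the selected SNPs, for users who want
  shrinkage only as a selection device.

### Numerical choices and degenerate inputs

* `s₀` defaults to the median of the `s_i`. If that median is exactly 0
  (degenerate panels where most SNPs are constant within classes), `s₀`
  falls back to the smallest positive `s_i`, or 1.0 when all dispersions
  vanish — keeping every distance and score finite; the constant rescales
  all scores uniformly, so predicted labels are unaffected.
* Mode ties are broken by the fixed category order `AA < Aa < aa <
  missing` (first maximum wins).
* A SNP constant everywhere has `f_ik = f_i`, hence `d_ik = 0`, and is
  never selected.
* When `d_ik = 0`, the shrunken distribution is defined as `f_i`.

### Missing handling

Missing genotypes are a first-class fourth category by default: they enter
the distribution vectors and one-hot indicators like any genotype. With
`include_missing=False` distributions run over the three genotype
categories only, missing calls are excluded from the per-SNP, per-class
denominators, and missing entries of a test sample contribute nothing to
its score. The 3-category mode raises an error when a SNP is entirely
missing within a class. The per-SNP missingness filter
(`filter_by_missingness`) drops SNPs whose missing fraction over all
samples exceeds a threshold (0.01 reproduces the "more than 1% missing"
exclusion rule used on genome-wide disease panels); it is idempotent and
order-preserving.

### Numeric baseline

`NumericShrunkenCentroid` recodes genotypes as missing=0, AA=1, Aa=2,
aa=3 and applies the classical continuous method — per-class means, pooled
within-class standard deviation, signed t-like statistic soft-thresholded
in absolute value — with the same selection/prediction API. It exists as
the comparison point for the categorical method, not as a recommended
estimator: the coding imposes an arbitrary ordering and spacing on
categories.

## Cross-validation

Samples are divided into `k=10` partitions whose sizes differ by at most
one; splitting is stratified by default (each class spread as evenly as
possible across folds), which avoids folds that miss a class at the sample
sizes typical for this problem. A *trial* is one random partition; the
default CLI runs 10 trials and averages. For each fold the model is fitted
once on the training samples and evaluated at every Δ on the grid (default
0 to 3 in steps of 0.1, spanning the useful range for these statistics;
shrinkage and scoring are cheap relative to fitting). Accuracy is
correctly classified test samples over all test samples.

`best_delta` is the largest Δ attaining the maximal mean accuracy — the
most parsimonious model among the accuracy maximizers. Because the curve
is evaluated on the test folds, the reported best accuracy is an
optimistic estimate of generalization; the full Δ–accuracy curve is
returned so users can apply their own rule. For SNP-*selection* tuning
(the use made of it here) this bias is benign: it picks a Δ near the
accuracy plateau, and recovery of planted SNPs is what the benchmark
checks.

## Epistasis test

For a binary trait and two SNPs coded as minor-allele dosages (0/1/2),
`logit P(case) = β₀ + β₁g₁ + β₂g₂ + β₃g₁g₂` is fitted by Newton/IRLS
(tolerance 1e−8 on the log-likelihood, at most 50 iterations). The report
is `β₃`, its Wald standard error from the inverse Fisher information,
`OR_int = exp(β₃)`, `χ² = (β₃/se)²` and the 1-df upper-tail P. Samples
with a missing dosage at either SNP are removed pairwise-complete and the
used count is reported. Any coefficient exceeding 15 in absolute value
flags (quasi-)complete separation; that, non-convergence, a single-class
response or a constant design column yield a flagged result with NaN
statistics rather than a number. χ² and P are invariant to which allele
the dosage counts; only the sign of β₃ depends on it. Raw P-values are
hard-thresholded (default 0.01) with no multiple-testing correction,
matching the screening convention this pipeline reproduces; the CLI's
output TSV appends a Bonferroni-adjusted column for transparency
(informational only — it plays no role in selection).

Calibration: under a null with main effects but `β₃ = 0` (n = 400, MAF
0.3/0.4, 1000 replicates) the empirical type-I error at α = 0.05 lands in
[0.03, 0.07]; a planted `β₃ = 1` at n = 500 with MAF in 0.3–0.4 is
detected at P ≪ 0.01. Power falls with MAF — at MAF near 0.1 few samples
carry a positive dosage product and n = 500 is not sufficient — which is a
property of the design, not the test.

## Gene similarity and networks

Information content is computed **from the supplied annotation corpus**:
`p(t)` = annotations to `t` or any descendant, divided by all annotations
in `t`'s namespace; `IC(t) = −log p(t)`. Namespace roots therefore have
`p = 1, IC = 0`, and `p` is monotone non-decreasing toward the root. Terms
with zero count borrow the smallest observed `p` in their namespace
(disable with `use_pseudo=False` to exclude them). Because the corpus is
user-supplied, similarity values — and any threshold chosen on them — are
corpus-relative.

Term similarity is the relevance measure: the Lin ratio
`2·IC(a)/(IC(t₁)+IC(t₂))` maximized over common ancestors `a`, weighted by
`1 − p(a)` so that sharing only a generic ancestor (the root) scores 0 and
identical specific terms approach 1. Gene similarity is the best-match
average of the two genes' term sets per namespace (molecular function and
biological process), combined across namespaces by arithmetic mean
(`max`/`min` available); a gene pair with no namespace in common is
undefined and excluded. Self-similarity of a gene can be below 1, and the
matrix diagonal need not dominate the off-diagonal.

Gene pairs with similarity **strictly greater** than the threshold are
linked; connected components with ≥ 2 genes are the gene groups (components
are the minimal structure consistent with pair-wise grouping — no further
clustering is imposed). SNPs located in grouped genes are scanned against
every SNP selected by the shrunken-centroid stage; pairs at P below the
cutoff form the SNP graph, and its components with ≥ 2 SNPs are the
reported networks. GraphML and edge-TSV exports carry `p`, `or_int` and
`chi2` losslessly; SIF carries topology only.

## Synthetic data: what it emulates and what it does not

The generator produces class-labeled panels shaped like small case/control
or population studies. Defaults (chosen once as the benchmark's study
conditions): 2 classes × 200 samples, 100 SNPs, 5 informative, missing
rate 0.005, null minor-allele frequencies Uniform(0.1, 0.5) under
Hardy–Weinberg proportions. Informative SNPs draw from explicit per-class
genotype distributions; the default pair (0.70, 0.25, 0.05) vs (0.35,
0.45, 0.20) has a total-variation gap of 0.35, comparable to the strongest
contrasts a selected real panel shows. For epistasis benchmarks, labels
are instead drawn from the logistic model on a planted pair's dosages (the
two mechanisms are deliberately not combined in one dataset: planted
marginal effects would confound the interaction benchmark). Everything
derives from one seed; the same spec and seed give byte-identical ped/map
output, and the `TruthManifest` records what was planted.

Not emulated: linkage disequilibrium between SNPs (calls are independent
across loci), trio/pedigree structure, genotyping batch effects,
population stratification within a class, and informative missingness
(missing calls are injected uniformly at random). Passing the recovery
benchmarks therefore shows the statistics behave as designed under clean
class structure — not that the method untangles correlated SNPs on real
panels, where LD will spread a signal across neighbours.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses the generator defaults above for the recovery
and chance-level runs (10 and 1 datasets of 400 × 100), 1000 replicates of
n = 400 for the type-I rate, and 5 datasets of 500 × 10 for the planted
interaction; the published confusion matrix and interaction statistic are
evaluated directly from the transcribed tables. The whole script runs in
seconds on one CPU.

## Known limitations

* Biallelic SNPs only; no dosage/probabilistic genotypes, no VCF or binary
  PLINK input.
* Δ tuning on the test curve (see above) — use an outer validation split
  if an unbiased accuracy estimate is required.
* The epistasis test is asymptotic; at small n or rare genotype
  combinations the Wald P can be anticonservative, and separation is
  reported as NA rather than resolved by penalization.
* Gene grouping depends on the annotation corpus supplied; thresholds do
  not transfer between corpora.
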