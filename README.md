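# snpshrink

Nearest-shrunken-centroid classification and relevant-SNP selection for
**categorical** genotype data, with a downstream pipeline that turns the
selected SNPs into interaction networks: pairwise logistic epistasis
testing, information-content GO semantic similarity for gene grouping, and
graph export for viewers such as Cytoscape.

## Who this is for

Genome-wide SNP panels have hundreds of thousands of markers and a few
hundred samples, and the genotypes are categories (`AA`, `Aa`, `aa`,
missing), not numbers. The classical nearest-shrunken-centroid classifier
assumes continuous features (per-class means); encoding genotypes as
0/1/2/3 and using it anyway discards the categorical structure. This
package implements the categorical variant: class centroids are genotype
*modes*, the operative centroid is the per-class genotype **distribution
vector**, and shrinkage acts on a standardized distance between class and
overall distributions. It is aimed at statistical geneticists doing
case/control or population classification who want a small, interpretable
panel of relevant SNPs and a view of how those SNPs interact.

## The model

For SNP *i* with per-class distribution vector *f<sub>ik</sub>* and pooled
distribution *f<sub>i</sub>* (frequencies over the genotype categories,
missing included as a fourth category by default):

```
d_ik  = || f_ik − f_i ||₂ / ( m_k · (s_i + s₀) ),     m_k = √(1/n_k − 1/n)
s_i²  = 1/(n−K) · Σ_k Σ_{j∈C_k} || e(x_ij) − f_ik ||₂²
d'_ik = max(d_ik − Δ, 0)                               (soft thresholding)
f'_ik = f_i + (f_ik − f_i) · d'_ik / d_ik              (shrunken centroid)
δ_k(t) = Σ_i || e(t_i) − f'_ik ||₂² / (s_i + s₀)² − 2·log π_k
```

where `e(·)` is the one-hot indicator of a genotype category, `s₀` guards
against SNPs with tiny dispersion (default: median of the *s<sub>i</sub>*),
`π_k` are class priors, and a test sample goes to the class minimizing
`δ_k(t)`. A SNP is *selected* at shrinkage Δ when any class keeps
`d'_ik > 0`; raising Δ gives a monotonically smaller panel. The shrinkage
amount is tuned by 10-fold cross-validation over a Δ grid. The classical
numeric-coding baseline (missing=0, AA=1, Aa=2, aa=3, per-class means and
t-like statistics) is included as `NumericShrunkenCentroid` for
comparison.

Downstream, SNP pairs are tested for statistical epistasis with a logistic
model on minor-allele dosages, `logit P(case) = β₀ + β₁g₁ + β₂g₂ +
β₃g₁g₂`, reporting `OR_int = exp(β₃)`, the 1-df Wald χ² and its asymptotic
P; pairs at P < 0.01 become network edges. Genes are grouped by thresholding
Rel-method semantic similarity (IC-weighted best-match average over the
molecular-function and biological-process ontologies).

## Worked example

```python
import snpshrink as ss
from snpshrink.crossval import default_delta_grid

# 2 classes × 200 samples, 100 SNPs of which 5 are informative
g, truth = ss.generate(ss.SyntheticSpec(seed=1))
print(truth.informative_snps)
# ['snp0015', 'snp0042', 'snp0048', 'snp0063', 'snp0088']

cv = ss.cross_validate(g, default_delta_grid(), seed=1)
print(cv.best_delta, round(cv.best_accuracy, 4))
# 0.8 0.7925

res = ss.ShrunkenCentroid(g).fit(cv.best_delta)
print(res.summary())
```

prints

```
Categorical nearest shrunken centroid
=============================================
samples: 400    SNPs: 100    classes: 2
categories: AA/Aa/aa/missing
delta: 0.8    s0: 0.758039
priors: case=0.500, control=0.500
SNPs selected: 11 / 100
top SNPs (max_k d'_ik):
  snp0088         2.8987
  snp0063         2.2241
  snp0048         1.7255
  snp0015         1.7088
  snp0042         1.6127
  ...
```

At the cross-validated Δ = 0.8 the panel shrinks from 100 SNPs to 11, and
the five planted SNPs are the five largest shrunken distances — the
statistic ranks true signal above every null SNP here. Held-out accuracy
0.79 reflects the planted effect size (total-variation gap 0.35 between
the class genotype distributions).

## Input formats

* **PLINK text ped/map** — whitespace-separated, `0` = missing allele,
  phenotype 1=control / 2=case (other values are kept as labels).
  Major/minor allele orientation is computed from the data; ties go to the
  lexicographically smaller allele.
* **Genotype TSV** — header `sample_id  label  <snp ids…>`, one row per
  sample, genotypes from `AA/Aa/aa/NN` (`aA` is accepted and
  canonicalized).
* **Ontology** — OBO 1.2/1.4 via obonet, plus a 2-column gene↔term TSV;
  `is_a` and `part_of` edges only.

A `snpshrink` console script wraps each stage
(`simulate`, `filter`, `fit`, `select`, `predict`, `cv`, `epistasis`,
`gosim`, `network`); see `snpshrink --help`.

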