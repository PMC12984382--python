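# Methods

This document describes the statistical methods implemented in
`omicsconcord` and the reasoning behind each choice. All notation: four
groups `F1F`, `F1M`, `wtF`, `wtM`; four canonical contrasts
`F1F_vs_F1M`, `F1F_vs_wtF`, `F1M_vs_wtM`, `wtF_vs_wtM`, each reported as
log2(first / second group).

## 1. RNA differential expression (`de_rna`)

**Normalization.** Median-of-ratios size factors: for each sample, the
median across genes of `count / geometric-mean-across-samples`, restricted
to genes with all-positive counts, then rescaled so the size factors have
geometric mean 1. This makes fold changes invariant to global sequencing
depth and is robust to a minority of highly expressed genes, unlike total
count scaling.

**Dispersion.** Per-gene method-of-moments estimates are pooled within
groups: for gene *g*,
`alpha_g = sum_groups((n_k - 1) * (s2_k - mean_k)) / sum_groups((n_k - 1) * mean_k^2)`,
clipped to [1e-8, 10]. Because per-gene estimates are noisy at these
replicate numbers (4–5 per group), a robust mean–dispersion trend
`alpha(mu) = a0 + a1 / mu` is fitted by iteratively reweighted least
squares with outlier down-weighting, and the final dispersion is a
geometric-mean shrinkage of the raw estimate toward the trend
(weight 0.5 in log space). Genes with zero mean in a group are flagged
and fall back to the trend.

**Test.** For each contrast, a two-parameter NB generalized linear model
(intercept + group indicator, log link) is fitted per gene by IRLS with a
closed-form 2×2 weighted-least-squares update; the coefficient is capped at
|beta| ≤ 30 natural-log units to stabilise separation cases (a group with
all-zero counts). The Wald statistic `beta / SE(beta)` is referred to the
standard normal. Genes with zero counts in all samples of the contrast are
excluded, not assigned p = 1, so they do not dilute the multiple-testing
correction.

**Calling.** A gene is a DEG when |log2FC| ≥ 1 and Benjamini–Hochberg
FDR < 0.05. BH is implemented in-package (step-up with suffix minimum,
clipped at 1) and verified in the tests against a brute-force
double-loop oracle.

## 2. Protein differential abundance (`de_protein`)

**Filtering.** Proteins are removed when flagged as contaminants, when
supported by fewer than 2 unique peptides, or when missing in more than
30 % of samples (strictly greater than — a protein at exactly 30 % is
retained). The filter report records counts per reason with the precedence
contaminant → peptides → missingness.

**Normalization.** log2 transform, then per-sample median centring on the
observed values. Median centring removes sample loading differences without
assuming any distributional form for the missing values.

**No imputation.** Missingness in label-free proteomics is intensity
dependent (missing not at random): low-abundance proteins drop out
preferentially. Imputing such values biases fold changes toward zero or
fabricates significance, so tests are computed on available cases only, and
proteins with fewer than 2 observed values in either group of a contrast
are excluded from that contrast.

**Test.** Moderated t statistics with empirical-Bayes variance shrinkage.
Residual variances `s_g^2` with `df_g` available-case degrees of freedom
are assumed to follow a scaled inverse-chi-square prior with parameters
(`d0`, `s0^2`), estimated by moment matching on `log s_g^2` using
digamma/trigamma identities (the trigamma inverse solved by Newton
iteration; `d0` capped at 1e6 when the observed variances are essentially
constant). The posterior variance
`(d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)` replaces `s_g^2` in the t
statistic, with `df_g + d0` degrees of freedom. This borrows strength
across proteins, which matters at 3–5 replicates per group.

**Calling.** DEP when |log2FC| ≥ 0.5 and BH FDR < 0.05. The lower fold-
change threshold relative to RNA reflects the compressed dynamic range of
protein-level log ratios.

## 3. RNA–protein integration (`integration`)

Pairs are built from the gene→protein map restricted to features tested at
both layers in the contrast; when several proteins map to one gene, either
all pairs are kept or the map is collapsed to the protein with the highest
mean intensity. Each pair is classified:

| class | rule |
|---|---|
| CONCORDANT_UP | DEG up and DEP up |
| CONCORDANT_DOWN | DEG down and DEP down |
| DISCORDANT | significant at both layers, opposite signs |
| RNA_EXCLUSIVE | DEG only |
| PROTEIN_EXCLUSIVE | DEP only |
| NS | significant at neither layer |

Directional agreement without dual significance is NS, not concordant:
concordance here is a statement about replicated *calls*, not about raw
sign agreement, which is near 50 % by chance.

Pearson and Spearman correlations of log2 fold changes are computed over
**all** pairs, not only significant ones, so the correlation is not
inflated by selection on effect size. Percentages are displayed with one
decimal, or two decimals when below 0.1 %, so that small non-zero shares
are not rounded to "0.0 %".

## 4. Ordered-query enrichment (`enrichment`)

Instead of testing a single DE cutoff, features are ranked by signed
log2 fold change (descending for UP, ascending for DOWN) and a
hypergeometric tail test is computed at every prefix length in
{10, 20, …, min(n, 1000)} plus the DE-cutoff prefix. The reported p-value
is the minimum over prefixes times the number of prefixes (Bonferroni),
so the score stays a valid p-value while being insensitive to the exact
cutoff. The universe is the set of tested features only — using the whole
genome as universe inflates enrichment for any well-measured category.
BH correction is applied across terms within each namespace. A term is
*concordant* when enriched in the same direction at both layers at the
chosen FDR.

The hypergeometric tail (k = 0 returns 1.0) is verified in the tests
against exhaustive enumeration of every instance with universe ≤ 60.

## 5. Differential methylation (`methylation`)

CpGs must have coverage strictly greater than 8 reads in every sample of
the contrast and non-degenerate pooled counts. Methylated and total reads
are pooled within each group and compared by a two-sided Fisher's exact
test; DM at BH FDR < 0.01. Pooling treats reads rather than animals as
the sampling unit, which is anticonservative under biological variability
— the stringent FDR threshold partly compensates, and the limitation is
deliberate: with 4–5 animals per group, per-animal beta-binomial models
are poorly identified. Degenerate margins give p = 1; log2 methylation
ratios use a 1/(T+1) floor to stay finite.

Genomic context comes from GFF3 or BED12 transcripts. Promoters are
[TSS − 2000, TSS + 500] oriented by strand; the precedence when a CpG hits
several features is promoter > exon > first intron > other intron >
intergenic, reflecting the relative regulatory weight of methylation in
each context.

## 6. Exploratory views (`exploratory`)

PCA is computed by SVD of the column-centred matrix (samples as
observations), reporting scores and percent variance; constant features
are dropped with a warning. Methylation PCA operates on per-CpG
methylation fractions. Heatmap ordering uses hierarchical clustering of
z-scored rows (zero-variance rows map to 0).

## 7. Synthetic data with ground truth (`synthetic_data`)

The generator reproduces the study conditions as defaults: 30,000 genes
with RNA replicates 5/5/5/4; 2,000 mapped proteins with replicates
5/5/5/3; methylation counts per CpG. Design principles:

* **Substreamed randomness.** Each stage draws from
  `default_rng([seed, offset])`, so changing one stage's size never
  perturbs another stage's data.
* **Symmetric effects.** Planted sex effect S and origin effect O enter
  group means as `base ± S/2 ± O/2`. The four canonical contrasts are then
  linearly dependent, so origin effects leak into sex contrasts at half
  size — a structural property of the 2×2 design, verified by test.
* **Sex-dominant design.** The sex-effect fraction and scale are large;
  origin effects are sparse and small, matching the intended biology.
* **Protein coupling.** Protein log effects are
  `c · rna_effect + sqrt(1 − c²) · ε` with a per-contrast target
  correlation c in [0, 0.3] by default. The noise draw ε for the sex
  component is shared across the two sex-bearing group differences, so
  that with c = 0 the protein layer carries no spurious origin signal.
* **MNAR dropout.** Protein missingness follows a logistic function of
  log intensity, so low-abundance values are preferentially missing.
* **Methylation.** Beta-distributed baseline methylation with a female
  logit offset at planted CpGs, binomial read sampling.

Ground truth (planted DE sets, true log fold changes, expected pair
classes) is returned alongside the data, enabling sensitivity/FDR checks
and coupling-recovery tests. For coupling recovery, the expected estimated
correlation is attenuated by estimation noise; the tests use the identity
`E[r_est] ≈ c_implied · corr(est_rna, true_rna) · corr(est_prot, true_prot)`
with reliability factors measured from the simulation itself, rather than
an additive-noise formula that fails for heavy-tailed effect
distributions.

## 8. Pipeline and reproducibility (`pipeline`, `cli`)

`run_all` executes simulate → RNA DE → protein DE → integration →
enrichment → methylation → exploratory, writing per-contrast TSVs and a
`manifest.json` containing stage summaries and SHA-256 hashes of every
output file, with sorted keys and no timestamps. Equal seeds therefore
yield byte-identical manifests, which the test suite asserts end to end.
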