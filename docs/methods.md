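# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the design decisions taken where the standard
methodology leaves room.

## Study design

The pipeline targets a three-group bulk-transcriptome design — lesional
skin, non-lesional (visually normal patient) skin, and healthy-control
skin — analyzed as three pairwise comparisons: lesional vs healthy,
lesional vs non-lesional, non-lesional vs healthy. Fold changes are always
case over reference, with the reference listed second in the comparison
name. Severity indices (EASI, 0–72; SCORAD, 0–103) exist only for lesional
samples; absence is encoded as missing, never zero.

## Differential expression

Counts are modeled as negative binomial, `K_gi ~ NB(s_i μ_g, α_g)`, with
sample size factors `s_i` from the median-of-ratios estimator (reference =
gene-wise geometric mean over zero-free genes; factors rescaled to
geometric mean 1). Genes with total count below 10 across all samples are
removed first — the threshold is interpreted as a whole-cohort total, the
common pre-filter idiom; a per-sample-mean variant is available via
`min_total`.

Dispersion is estimated per gene by the method of moments on normalized
counts, `α̂ = max(ε, (s² − μ̄)/μ̄²)` with `s²` the pooled within-group
variance, `μ̄` the grand mean and `ε = 1e-8` (the Poisson floor). Gene-wise
estimates are then shrunk 50/50 on the log scale toward a log-linear trend
of dispersion on mean expression (OLS of log α̂ on log μ̄, fit over genes
off the floor). The geometric form of the 50/50 blend follows from the
trend being log-linear. The shrinkage stabilizes low-information genes and
is mildly conservative for Poisson-like genes, which the trend pulls up;
measured on a 2000-gene null cohort (27/27/38 samples) the raw p < 0.05
rate is ~5%, inside the 3–7% band asserted in the acceptance suite.

The test itself is a closed-form two-group Wald test: group means `μ̂_A,
μ̂_B` of normalized counts, `log₂FC = log₂((μ̂_B + c)/(μ̂_A + c))` with a
moderation constant `c = 0.5` normalized counts so all-zero groups give a
bounded fold change, a delta-method standard error
`Var(μ̂_g) = n_g⁻² Σ_i (μ_g/s_i + α_g μ_g²)` propagated through the log,
and a two-sided normal reference. BH correction is applied over all
post-filter genes (no independent filtering), and a gene is significant at
adjusted p < 0.05 and |log₂FC| > 1. This deliberately implements the
statistical content of the standard NB differential-expression workflow —
NB model, Wald test, BH — rather than any particular package's additional
machinery (IRLS GLM fits, Cox–Reid dispersion adjustment, fold-change
shrinkage, outlier replacement); those are out of scope and their absence
is visible mainly as slightly less power at very small n.

## Hypervariable genes and normalization

Network stages run on `log₂(count/s_i + 1)` values. This is a monotone
variance-stabilizing transform; every downstream consumer uses only
correlations, means, ranks or linear fits, which are insensitive to the
choice among monotone stabilizers. The transform applied is recorded in
`ExpressionMatrix.transform_tag`; the pipeline always filters before
normalizing (size factors are computed on the filtered matrix).

Each pairwise comparison selects its own hypervariable genes: CV =
100·sd/mean > 15% computed on the normalized scale over that comparison's
samples. Whether the published single hypervariable-gene count refers to a
union, intersection or whole-cohort computation is not stated in the
methodology this follows; per-comparison selection is the default here and
a whole-cohort CV is available by passing the full expression matrix.
Genes with non-positive mean on the normalized scale have no meaningful CV
and are excluded.

## Co-expression network

Similarity is Pearson correlation between gene profiles; the network is
**unsigned**, `A_ij = |S_ij|^β` — raising a signed correlation to an odd
power would produce negative adjacencies, so the unsigned convention is
the only consistent reading and matches the standard weighted-network
default.

β is chosen by the scale-free topology criterion: for each power 1–20,
connectivity `k_i = Σ_{j≠i} A_ij` is binned into 10 equal-width bins and
log₁₀(bin frequency) regressed on log₁₀(mean bin connectivity); signed
R² = R² × (−sign(slope)). The smallest power with signed R² ≥ 0.85 wins.
Two guards matter in practice: (i) equal-width bins — equal-count bins
make the bin frequency constant by construction and the regression
degenerate; (ii) powers whose mean connectivity falls below 1 edge per
gene are excluded from the search, because a vanishing network fits a
power law trivially while carrying no clusterable topology. When no power
qualifies (block-structured synthetic data is not scale-free, so this is
the norm on generated cohorts), the best-fitting usable power is taken
with a logged warning.

TOM is computed exactly as
`TOM_ij = (ℓ_ij + A_ij)/(min(k_i,k_j) + 1 − A_ij)` with
`ℓ_ij = Σ_{u≠i,j} A_iu A_uj`, unit diagonal, zeroed diagonal for
connectivity; the vectorized form is checked against a double-loop oracle
to 1e-10.

### Module detection

Average-linkage hierarchical clustering of 1 − TOM, followed by a
deterministic two-stage cut:

1. **Cores.** The merge sequence is scanned with union–find for the
   earliest partition containing the maximal number of clusters with at
   least `min_module_size` (50) members. Early states keep branches tight;
   background genes attach higher in the tree, so the winning state holds
   pure module cores.
2. **Membership completion.** Every network gene is assigned to the core
   whose eigengene it correlates with most strongly in absolute value,
   *provided* that correlation is significant under Bonferroni control at
   α = 0.05 across all gene × core tests. Genes failing the test stay
   unassigned, so noise genes are not absorbed by tree proximity alone.
   The minimum-size rule is re-applied afterwards.

A fixed-height cut (any quantile of merge heights) was implemented and
measured first: on realistic generated cohorts background genes attach to
module branches *below* any single cut height — the geometry that
motivated dynamic branch-cutting methods — and the static cut returns one
giant cluster. The two-stage procedure recovers 3×100-gene planted blocks
at adjusted Rand index 0.99–1.00; the quantile cut remains available via
`cut_quantile` for cases where the correct height is known. Modules are
labeled M1, M2, … by decreasing size, with conventional color aliases
(turquoise, blue, brown, …) for reporting; on unsigned networks two
anti-correlated planted modules can legitimately merge into one detected
module, since |cor| links them.

### Module–trait association and DCEGs

A module eigengene is the first right singular vector of the standardized
(per-gene zero-mean, unit-variance) member submatrix, unit norm, sign
aligned with the member-wise mean profile. Eigengene–phenotype association
uses Spearman correlation with the binary comparison coding (reference 0,
case 1): t-approximation p-values for n ≥ 10, exact enumeration of all
case/control assignments below that. A module is selected at |R| > 0.5 and
p < 0.05. DCEGs are the intersection of significant DEGs with selected
module members, reported per module and as a per-comparison union.

## Over-representation and pathway expression

Enrichment of a DCEG list is the one-sided hypergeometric upper tail
against each gene set, with both set and query restricted to the tested
universe (all post-filter genes of the comparison), BH across retained
sets, enriched at adjusted p < 0.05. A raw-p mode exists because both
conventions appear in practice for "over-represented pathways (p < 0.05)";
the adjusted mode is the default.

Pathway expression is the arithmetic per-sample mean of the pathway's
annotated genes restricted to the DCEG union (an "all annotated genes"
mode serves validation matrices). The exact gene list averaged is
persisted with the matrix, and validation cohorts are scored on those
frozen discovery lists, restricted to genes present (a pathway is dropped
below 50% coverage) — the frozen-list convention is this package's
declared behavior where the original procedure is ambiguous.

## Random-forest pathway ranking

The classifier is a bagged ensemble of CART trees (default 500), √p
features per split, unlimited depth, no class weights — the defaults of
the classic R implementation. The bagging and out-of-bag bookkeeping are
implemented in this package (each tree's bootstrap indices are drawn from
the seeded generator) so that importance is genuinely out-of-bag:
out-of-bag accuracy is the majority-vote accuracy over trees for which a
sample was not drawn.

Importance of a pathway is the **mean decrease in accuracy in percentage
points**: the OOB accuracy is re-evaluated after permuting that pathway's
column, 20 independent permutations by default, and
`importance = 100 × (baseline − mean permuted accuracy)`, unscaled (not
divided by its SD). On a 0–1 accuracy scale a threshold of 4 would be
unsatisfiable; in percentage points a perfectly separating feature scores
near `100 × (baseline − chance)` ≈ 55+ on a balanced-ish three-group
cohort, so the "> 4" selection cutoff is meaningful and strict (ties at
exactly 4 are not selected). Selection order is decreasing importance,
ties broken by name.

## Evaluation and replication

Group differences in pathway expression use two-sided Welch t-tests (the
safer default where only "t-tests" is specified; Student's form is a
one-line change), with the conventional star bands (< 0.05 *, < 0.01 **,
< 0.001 ***, < 0.0001 ****). Severity association is Pearson correlation
over samples with non-missing EASI/SCORAD (≥ 5 required). Diagnostic AUC
fits a univariate logistic model and computes the AUC of its scores by the
Mann–Whitney rank formula with the ½ tie correction; because the logistic
score is monotone in the feature, this must equal the feature's own rank
AUC, and the implementation asserts that identity on every call (complete
separation is caught and the rank AUC used directly). AUCs are reported
oriented (≥ 0.5) with a direction flag, and are in-sample — fit and
evaluated on the same cohort, which is optimistic; no cross-validation is
attempted. A signature *replicates* when it is significant (p < 0.05) with
the same direction of change in both cohorts.

## Synthetic cohorts

`generate_cohort` draws gene baseline log₂ means from N(5, 1.5) (median
~32 counts), library-size factors log-normal with σ = 0.15 (±30%), and
counts via the gamma–Poisson mixture at a shared dispersion of 0.2 — a
realistic value for heterogeneous bulk tissue, and the value at which the
CV > 15% filter behaves as it does on real data (planted-module genes
retained at ~95%, background at ~30%; at lower dispersion the log-scale CV
statistic discards highly expressed module genes and the generated data
lack the structure the hypervariable step assumes).

Co-expression is induced on the log-mean scale by a per-module latent
Gaussian factor `z_m`; the member loading is calibrated from the
delta-method NB log-variance so the average pairwise Pearson correlation
on the normalized scale hits the requested `intra_module_cor` (default
0.6), accounting for the factor's between-group variance. Modules planted
with a phenotype association give `z_m` a group-dependent mean; the
default shift is 3 SD, chosen so associated-module genes carry induced
|log₂FC| ≈ 1.0–1.5 — i.e. module members are simultaneously DEGs, the
defining property of a DCEG — while the module–trait gate fires at
|R| ≈ 0.8. The three default modules cycle the patterns +lesional,
−lesional, +non-lesional. Explicit DE genes (default 5% of the
transcriptome at |log₂FC| = 2) are planted outside modules, two-thirds
shifted in lesional, one-third in non-lesional. All induced and explicit
fold changes are recorded per comparison in the truth object.

`generate_gene_sets` builds one informative set per associated module
(~80% of members drawn from the module, ≥ 5 planted genes) plus decoys
capped at ~10% planted-module membership. `generate_severity` assigns
lesional-only EASI = 10 + 8·z + ε and SCORAD = 25 + 10·z + ε (truncated at
0), driven by the first positively-lesional module's latent factor; at the
default noise SD of 4 the signal-to-noise ratio is 2:1.
`generate_validation_cohort` redraws samples, latent factors and counting
noise from the same gene-level truth (default 29/40/39 group sizes, the
shape of a typical microarray replication cohort).

What the generator does **not** emulate: GC/length bias, batch effects,
microarray noise models, correlated library-size/condition confounding,
gene–gene correlation outside planted modules, and realistic pathway
overlap topology. Passing recovery tests therefore certifies the
statistical machinery under the stated model, not robustness to those
artifacts.

## Problem sizes and numerical choices

The default generated cohort is 5000 genes × 92 samples (27/27/38); the
full pipeline runs in well under a minute on one CPU and is
bit-reproducible given a seed (the forest is the only stochastic stage and
derives every tree's randomness from the seeded generator). Recovery
simulations in the test suite use 1500–2000 genes and 10–20 seeds per
property, sizes at which the Monte-Carlo assertions are stable.
Miscellaneous numerics: dispersion floor 1e-8; fold-change moderation 0.5
normalized counts; correlations clipped to [−1, 1]; TOM clipped to [0, 1]
with unit diagonal; dendrogram tie blocks (equal merge heights) are never
split by the core scan; Bonferroni (not BH) controls module-membership
completion because the module genes' extreme correlations would otherwise
drag the BH threshold toward absorbing background genes.

## Known limitations

- The NB Wald test has no covariate adjustment or outlier handling; it is
  a two-group caller.
- In-sample AUCs overstate out-of-sample discrimination.
- Unsigned networks merge anti-correlated modules by design; a
  signed-network option is the natural extension point.
- The scale-free criterion rarely qualifies on block-structured synthetic
  data, so generated-cohort runs typically use the best-fit fallback power
  (logged); on real transcriptome data the criterion behaves as usual.
- Exact permutation p-values in the module–trait test are limited to
  n < 10; above that the t-approximation is used.
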