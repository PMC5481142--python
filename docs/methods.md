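# Methods

## Model

We work with standardized data: the phenotype `Y` (length N) and every
genotype column of `X` (N × M) have mean 0 and variance 1, under the
additive model `Y = X β + ε`.  Marginal GWAS estimates are
`β̂ = XᵀY / N`, so the association chi-square of SNP i is `χ²_i = N β̂_i²`
and the sample LD matrix is `D̂ = XᵀX / N`.

### Heritability partition

Given K binary annotation tracks `S_1 … S_K` plus `S_0` = the whole
genome, we assume additivity of per-SNP heritability across overlapping
annotations: `β_i ~ N(0, Σ_{j: i∈S_j} τ_j)`.  Then

    E(χ²_i) ≈ (N − 1) Σ_k τ_k l(i,k) + 1,

where `l(i,k) = Σ_{j ∈ window(i), j∈S_k} r²_ij` is the
annotation-stratified LD score (the SNP itself included, so
`l(i,0) ≥ 1`).  We fit τ by weighted least squares of `χ² − 1` on
`(N−1)·l` with no intercept (the chi-square intercept is pinned at its
null value 1) and weights `1 / max(1, l(i,0))²`; standard errors come
from a delete-one-block jackknife over 200 contiguous SNP blocks.  When
the supplied tracks exactly partition the genome the `S_0` column is a
linear combination of the others; we then drop it from the regression
(reported as `τ_0 = 0`) instead of failing on collinearity.  Any other
rank deficiency raises a multi-collinearity error, because overlapping
tracks genuinely make the coefficients unidentifiable.

Total chip heritability uses the summary-statistic moment estimator

    Ĥ² = M (χ̄² − 1) / (N l̄),

with `χ̄²` the mean chi-square and `l̄` the mean genome LD score, clamped
to [0.001, 1] with a warning (a proper prior needs Ĥ² > 0).  Per-SNP
heritabilities `h²_i = Σ_{j: i∈S_j} τ̂_j` are floored at
`1e-9 · Ĥ²/M`, since WLS can produce negative sums for individual SNPs.

Enrichment of annotation k is
`fold_k = (Σ_{i∈S_k} h²_i / Σ_i h²_i) / (|S_k| / M)`; its p-value is a
two-sided z-test with the jackknife SE of the fold.  The exact test
behind published enrichment p-values of this kind is not standardized;
the block jackknife is the conventional choice and is what we use.

### Empirical priors

Both priors are spike-and-slab mixtures whose implied total
heritability equals Ĥ² exactly (unit tested at 1e-10):

1. **Per-SNP variance**: `β_i ~ p₀ N(0, σ̂²_i/p₀) + (1−p₀) δ₀` with
   `σ̂²_i = c·h²_i`, `c = Ĥ² / Σ h²_i`.  The constant c rescales
   regression-context heritabilities to the analyzed SNP panel; it makes
   the prior invariant to any positive rescaling of the per-SNP
   heritabilities.
2. **Per-combination causal fraction**: every causal SNP has variance
   `V = Ĥ²/(p₀ M)`, but the causal fraction varies over
   annotation-combination classes `T` (SNPs sharing an identical track
   membership pattern): `p_T = p₀ M H²_T / (M_T Ĥ²)` with
   `H²_T = Ĥ² · (class share of Σ h²_i)`.  Fractions are clipped to
   `[1e-6, 1]`; whenever clipping binds, the class slab variance is
   rescaled so the class identity `H²_T = p_T M_T V_T` still holds.
   Combination classes smaller than 10 SNPs (configurable) are merged
   into their nearest superset class to avoid dividing by tiny `M_T`.

With a single genome-wide annotation — or constant enrichment, i.e.
equal per-SNP heritabilities — both priors collapse to the classic
uniform spike-and-slab and the whole pipeline reduces to an
LDpred-style model (property-tested, and exercised end-to-end by the
constant-enrichment study).

`p₀` is a tuning parameter; the default grid is
{1, 0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4, 1e-4} and both prior
variants are tuned over jointly.

### Posterior effects

The genome is cut into contiguous blocks of `⌈M/3000⌉` SNPs (singleton
blocks when M ≤ 3000).  Within a block,

    β̂_b | β_b ~ N(D̂_b β_b, (1 − h²_b)/N · D̂_b),

where `h²_b` is the block's prior heritability `Σ p_i v_i`
(capped at 0.9 so the noise variance stays positive) and `D̂_b` is the
correlation matrix of the block in the reference/validation panel
(diagonal forced to exactly 1; optional ridge shrinkage
`(1−λ)D + λI`).  Each coordinate's full conditional given the others is
derived by conjugacy from the residualized marginal
`β̃_i = β̂_i − Σ_{j≠i} D̂_ij β_j`, which is `N(β_i, s²)` as a function of
β_i with `s² = (1−h²_b)/N`: a two-component mixture of δ₀ and
`N(β̃_i v_i/(v_i+s²), v_i s²/(v_i+s²))` with posterior inclusion odds
`p_i/(1−p_i) · √(s²/(v_i+s²)) · exp(β̃_i² v_i / (2 s² (v_i+s²)))`.
A systematic-scan Gibbs sampler (default 100 post-burn-in iterations,
60 burn-in, initialized at β̂_b) averages the draws.  Correctness of the
conditional is not taken on faith: an independent oracle enumerates all
2^|b| spike/slab configurations, computing each configuration's exact
Gaussian marginal likelihood and conditional mean, and the sampler is
required to agree within 3 Monte-Carlo SEs on random blocks of up to 8
SNPs.  Monte-Carlo SEs in that check use Geyer's initial positive
sequence estimator, the standard (mildly conservative) choice for
reversible MCMC chains.

Equal-size blocks are sampled in vectorized batches; the random stream
is split per batch from a single seed, so results are bit-reproducible
given the seed.  A chain whose mean leaves 10× the marginal-effect
range aborts with a message recommending LD shrinkage λ = 0.1.

### Scoring, tuning and evaluation

`PRS_i = Σ_j x_ij w_j` on standardized genotypes.  Hyperparameters
(prior variant, p₀, or the pruning/threshold pair) are tuned by a
split-half scheme on the phenotyped validation cohort: choose the
candidate maximizing COR (Pearson correlation of PRS with the observed
phenotype, 0/1 for case-control) on one random half, evaluate on the
other, swap roles, and average the two held-out metrics.  Binary splits
are stratified by case status when a random split is degenerate.
Metrics: COR, AUC (rank-based), top-5% case enrichment, and a nested
logistic likelihood-ratio test (`pheno ~ PRS1` vs `pheno ~ PRS1 +
PRS2`, χ²(1)), run in both orders; a perfectly collinear addition is
reported as p = 1 (zero added rank implies zero added likelihood), and
separation/non-convergence as NaN.

Baselines: all-SNP marginal weights; genome-wide-significant SNPs only
(p < 5e-8, NaN when none reaches significance); pruning+thresholding
with greedy clumping (ascending p-value order, a retained SNP removes
unvisited neighbours with r² above the threshold) tuned over r² ∈
{0, 0.1, …, 0.9} × p ∈ {1, 0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4,
1e-4, 3e-5, 1e-5, 1e-6, 1e-7, 5e-8, 1e-8}; and the genome-only
(LDpred-style) special case of the main model.

## Synthetic data

The generator emulates a common-variant case: MAF ~ U(0.05, 0.5)
(post-QC GWAS arrays contain mostly common variants), diploid dosages
from two haplotype draws of a Gaussian copula with equicorrelation ρ
(default 0.5) inside contiguous blocks of 10 SNPs, giving
Binomial(2, f) marginals with block LD.  K = 2 binary annotations each
mark an exact uniform-random 10% of SNPs.  Causal SNPs (default 300)
are allocated one third to each annotation and one third to the rest of
the genome — a strong enrichment; effects are `N(0, h²/m)`; noise is
rescaled empirically so the realized genetic variance share equals h²
exactly in each replicate (the alternative, fixed-variance noise,
differs only by O(1/√N) and would add replicate-level jitter to the
quantity under study).  A liability-threshold option produces binary
traits at a chosen prevalence (default 0.5, mimicking balanced
case-control designs).  70% of individuals provide training summary
statistics; the remaining 30% form the validation cohort whose two
halves drive the split-half tuning.

What the generator does **not** emulate: realistic human LD maps (long-
range LD, variable block sizes), population structure, relatedness,
allele-frequency/effect-size coupling, genotyping error or
missingness-by-ancestry.  Passing tests therefore demonstrate internal
correctness and the comparative behavior of the methods under the
stated generative model, not real-data performance.

## Study scales and numerical choices

Validation studies run at desk scale, chosen so each property is
measured with meaningful Monte-Carlo precision:

* sampler-vs-enumeration: 100 random blocks of ≤ 8 SNPs, 4000
  post-burn-in iterations;
* heritability recovery: M = 20,000 independent SNPs, N = 5,000, two
  10% annotations, 20 trait replicates per h² ∈ {0.25, 0.5};
* method comparison: M = 10,000, N_train = 3,000 (70% of ~4,286),
  m ∈ {100, 1,000} causals, h² ∈ {0.25, 0.5}, 20 replicates; the
  genotype panel is generated once per setting and traits are re-drawn
  per replicate, as in designs where genotypes come from a single fixed
  cohort; LD scores and pruning LD come from the full panel, block LD
  from the validation subset;
* constant-enrichment equivalence: same scale, causals uniform, two
  complementary half-genome annotations, pooled permutation test
  (10,000 relabelings) on the AnnoPred-vs-LDpred COR replicates;
* effective-sample-size sweep: M = 6,000, N_train = 1,200, causal
  subsets of 100% / 50% / 25% of SNPs at fixed causal proportion 0.01
  and h² = 0.5.  N_train is deliberately small so all three effective
  sizes (1,200 / 2,400 / 4,800) sit on the rising part of the accuracy
  curve; at larger N the top of the sweep saturates near the COR
  ceiling √h² and the monotonicity comparison degenerates into noise.

In simulations LD windows are 50 SNPs to each side (the generator's LD
range is 10 SNPs); on real coordinates the default window is a 1 Mb
radius.  r² is used unadjusted by default; the small-sample correction
`r² − (1−r²)/(N−2)` is available.  LD-score sums are accumulated in
float64 against exact per-column norms so they match a direct pairwise
computation to machine precision even though panels are stored in
float32.

## Other design decisions

* Missing genotypes are mean-imputed per SNP before standardization;
  monomorphic SNPs are dropped (variance-1 scaling is undefined).
* Duplicate SNP ids keep the first occurrence with a warning.
* Strand-ambiguous (A/T, C/G) SNPs are dropped at harmonization;
  non-palindromic strand mismatches are resolved by complementing.
* Coordinates are 1-based; region exclusion (e.g. the chr6 MHC
  interval 28,477,797–33,448,354) uses a closed interval, matching the
  PLINK bim convention.
* Continuous annotation scores are smoothed with a centered 10 kb
  moving mean (truncated at chromosome ends) and dichotomized at a
  strict 0.5 cutoff.
* The pipeline seed fans out into named per-stage substreams, so
  changing e.g. the sampler iteration count does not perturb the
  simulated cohort.

## Limitations

Cross-block LD is ignored (blocks are disjoint, no overlapping
windows); posterior uncertainty of τ is not propagated into the priors;
binary-trait COR is computed on the observed 0/1 scale without
liability transformation; absolute-risk calibration is out of scope.
With many highly overlapping annotation tracks the stratified
regression becomes ill-conditioned — the package raises an explicit
multi-collinearity error rather than returning unstable coefficients.
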