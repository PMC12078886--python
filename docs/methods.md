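# Methods

## Scope and data model

The package operates on an accessions × SNPs allele-dosage matrix
(`GenotypeMatrix`) and long-format accession × trait × year phenotype
records. Dosage counts copies of the alternate allele (the second allele of
a HapMap `alleles` field); since every model centers marker columns, this
convention only fixes effect signs. Positions are 1-based; calls are taken
as reported (no strand flipping). Quality control retains SNPs with call
rate strictly above 0.90 and minor allele frequency strictly above 0.05
(both configurable); missing dosages are then mean-imputed per SNP — array
data are nearly complete, and mean imputation is the cheap, standard choice
for genomic prediction, where downstream centering makes imputed entries
contribute nothing to effect estimation on average.

## Phenotype adjustment and heritability

Traits observed over two years are adjusted with

    P_ik = mu + Y_i + g_k + e_ik,

year fixed (sum-to-zero coding, so `mu` is the grand mean), genotype
random. The model has a single random factor, so REML is a 1-D profiled
likelihood in `gamma = sigma2_G / sigma2_eps`, solved on the eigenbasis of
the genotype incidence cross-product (grid bracketing + bounded Brent;
`xatol` 1e-10). Negative variance estimates are clamped at the `gamma = 0`
boundary and flagged. For balanced data the estimates equal the two-way
ANOVA method-of-moments estimators (tested to 1e-6); unbalanced records go
through the same fit (cross-checked against an independent mixed-model
implementation). Broad-sense heritability on genotype means over `n_y`
years is

    H2 = sigma2_G / (sigma2_G + sigma2_eps / n_y).

Single-year traits cannot separate genotype from residual and pass through
unadjusted with no H². The adjusted value handed to prediction is
`mu + BLUP(g_k)`.

## Whole-genome regression models

**rrBLUP.** With centered dosages `X` and fixed design `W` (intercept +
optional cofactor SNPs), variance components of
`y = W b + X u + e, u ~ N(0, sigma2_u I)` are REML estimates obtained on
the spectrum of the projected kinship `S X X' S` (the classical spectral
algorithm; one 1-D optimization in `delta = sigma2_e / sigma2_u` over a
61-point log grid refined by bounded Brent). Marker effects are recovered
as `u = X'(XX' + delta I)^-1 (y - W b)`, so cost is O(n^2 m + n^3)
regardless of marker count. Predictions are identical (tested to 1e-8) to
GBLUP with the cross-product kinship. A constant phenotype yields the
degenerate fit `u = 0`, intercept = mean, with a warning. Collinear
cofactors are rejected by a rank check naming the offending columns.

**Bayesian alphabet.** All five models share one single-site Gibbs sampler
(numba kernel, incremental residual updates; ~2 s per 6000-sweep chain at
n = 170, m = 1000 on one core) and differ only in the marker-effect prior:

| model | prior on u_j | extra state |
|---|---|---|
| BRR | N(0, s2u), common s2u ~ scaled-inv-chi2 | – |
| BayesA | N(0, s2_j), per-marker scaled-inv-chi2 | m variances |
| BayesB | pi-mass at 0 + BayesA slab | indicators + variances |
| BayesC | pi-mass at 0 + common-variance slab | indicators |
| BL | double-exponential (normal-exponential mixture) | local tau2_j, lambda2 |

`pi` is the prior probability of a zero effect (default 0.5, fixed; an
opt-in beta update is provided but off by default so chains have a fixed,
interpretable sparsity level). Hyperprior scales follow the
variance-partition convention: prior modes are set so markers explain
r2 = 50% of the phenotypic variance (divided by the expected included
fraction for the spike-and-slab models), residual the rest; df = 5 for both
marker and residual scaled-inv-chi2 priors. The Bayesian LASSO
regularization `lambda2` gets a Gamma(1.1, rate) prior centered on the same
r2 budget and is updated each sweep (inverse-Gaussian draws for the local
scales, with a 1e-12 floor on u_j^2 for numerical safety). Defaults are
6000 sweeps with 1000 burn-in. Convergence is monitored by the split-chain
potential scale reduction factor of sigma2_e; Rhat > 1.1 raises a warning
flag (`converged_ = False`), never an error. Chains are seeded per fit;
cross-validation derives per-repetition seeds from the scheme seed, so
whole experiments are exactly reproducible.

Fixed-effect cofactor SNPs (GWAS peaks) are removed from the random marker
set by default to avoid counting a locus twice; `keep_in_random` restores
the alternative since either protocol is defensible.

## Cross-validation and density ladders

Accuracy is the Pearson correlation between predicted and observed adjusted
phenotypes in the hold-out (undefined for constant vectors; such
repetitions are recorded as missing with a warning). Partitions are
repeated random splits without stratification; hold-outs below 3 accessions
are rejected. The SNP ladder keeps the top fraction of markers ranked
either by estimated variance contribution `u_j^2 Var(x_j)` from an rrBLUP
fit (effect_variance) or by expected genotype variance `2p(1-p)`
(genotype_variance); ties break deterministically by chromosome and
position. Ranking is computed inside each training partition so marker
selection never sees the hold-out; `rank_on_all=True` reproduces the
simpler rank-once protocol for comparison. Reported summaries are the mean
and the unbiased (n−1) SD over repetitions; printed percentage gains of an
optimized design over random, `(opt − random)/random × 100`, are rounded to
the nearest integer, halves away from zero.

## Training-set optimization

The VanRaden relationship matrix uses panel allele frequencies; monomorphic
SNPs are excluded from the denominator with a warning. For a candidate
training/validation split, with `lambda = sigma2_e / sigma2_g`:

    V = G_tt + lambda I
    PEV_i = G_ii − c_i' P c_i,   CD_i = 1 − PEV_i / G_ii,

where `c_i = G_t,i` and `P` is `V^-1` projected orthogonal to the intercept.
This GLS form equals the classical expression through the inverse
coefficient matrix of the mixed-model equations whenever `G` is
nonsingular, and remains well defined for the centered GRM (always rank
n − 1); a singular `V` receives a 1e-8 ridge jitter with a warning. Note
CD includes the intercept-estimation share of the error, so even a
validation accession duplicated in the training set has CD slightly below
1 (by roughly 1/n_train). `lambda` defaults to the REML ratio from a
preliminary rrBLUP fit on all phenotyped accessions (fallback 1.0,
i.e. h² = 0.5).

CDmean (maximize) and PEVmean (minimize) are searched with a seeded genetic
algorithm — tournament selection (size 3), uniform crossover with size
repair, exchange mutation (rate 0.02), elitism 5, population 100 × 200
generations by default — whose initial population contains the best of 100
random designs, so the returned design never scores below that baseline.
MeanRel (maximize mean training-validation relatedness) is solved exactly
by enumeration when the design space has at most 50,000 subsets, and
otherwise by deterministic greedy forward selection with a
first-improvement swap refinement; both paths return the identical design
on every run, which is why repeated cross-validation under MeanRel has
zero accuracy dispersion. SVD reduction of the genotype matrix is provided
as a compatibility mode: accession scores on the top singular vectors
reproduce the cross-product kinship exactly at full rank.

## The MAS-vs-GS rule

Per trait: MAS is suggested when the cumulative explained-variance
percentage of the top (at most three) significant GWAS SNPs exceeds 30;
GS when mean GP accuracy exceeds 0.40; both thresholds strict and
configurable. A literal variant ("fewer than three SNPs explain > 30%") is
implemented for comparison but is not the default: it fails on traits
tagged by exactly three strong SNPs, which the cumulative reading handles
consistently. The bundled 25-trait walnut reference table (GWAS summaries,
accuracies, and reported recommendations) is reproduced label-for-label by
the cumulative rule.

## Synthetic panels

The generator emulates a walnut-like core collection: 170 diploid
accessions, 16 chromosomes of 1 Mb carrying 10,000 SNPs in total (a
desk-scale mirror of a 364k array — ladder *fractions* are preserved, so
the 1% rung is ~100 SNPs), MAF floor 0.05, observed heterozygosity within
±0.05 of 0.3. Founder haplotypes (default 32) are drawn by thresholding an
AR(1) latent Gaussian field whose correlation decays as
`exp(−2e-5 per bp × distance)`; panel haplotypes copy founder segments with
recombination switches at 3e-6 per bp (~3 per chromosome). The copying
process is what creates identical-by-descent sharing between accessions —
the GRM has mean diagonal ≈ 1 with off-diagonal structure — and with it the
two ingredients of GP accuracy: relatedness and marker-QTL association.
Minor-allele-frequency floors are enforced by redrawing founder alleles
(bounded retries) and finally by flipping the heaviest-used founders'
alleles, so LD and relatedness survive the repair.

Trait architectures: `n_qtl` causal SNPs, the first ones optionally scaled
to per-QTL explained-variance targets (fraction of the genotype-mean
phenotypic variance, the scale GWAS "PEV%" is reported on; a three-step
fixed-point rescale hits targets within ±0.03), the remainder a polygenic
tail filling the genetic variance. The default polygenic QTL count is 30:
the panel is a ~1/36 scale model of the dense array, and scaling the QTL
count equally preserves the marker:QTL ratio that produces the observed
1%-rung accuracy plateau. Residual variance follows from the H² identity
(empirically rescaled, so realized components reproduce the target H²
essentially exactly); phenotypes are generated under the same year +
genotype model the adjustment stage fits, so that stage is correctly
specified by construction — model misspecification is deliberately out of
scope.

What the simulator does **not** model: population structure or admixture
(the emulated collection showed K = 2 with no trait effect), pedigree
families, genotyping error, dominance/epistasis, G×E. Consequences for
test interpretation: passing accuracy tests show the estimators exploit
relatedness and LD correctly, not that real-data accuracies will match;
and one documented direction from field data — accuracy dispersion across
repetitions increasing at 50% training — does not reproduce on this
exchangeable panel, because the Pearson-correlation sampling noise
(∝ 1/√n_validation, smaller at 50/50) dominates once training-composition
instability from family structure is absent. The corresponding acceptance
check is left failing rather than weakened; the major-locus trait subset
does reproduce the direction.

## Problem sizes and numerical choices

Test-suite experiments use the 170 × 10,000 desk panel for ladder and
training-size checks, 170 × 1000–4000 panels for model equivalences and
heritability recovery (50 replicates), and 12-accession panels for
enumeration-backed optimizer checks; these sizes were chosen so the full
suite documents the science at interactive turnaround. Numerical
tolerances: 1e-8 for linear-algebra equivalences, 1e-6 for REML-vs-ANOVA,
±0.05 for heritability recovery, ±0.03 for per-QTL variance targets.
Degenerate inputs (constant phenotypes, monomorphic markers, fully missing
columns, singular kinships) are handled explicitly as described above.
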