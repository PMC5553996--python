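# Methods

## Model and estimation

The phenotype is a 0/1 case indicator analysed on the observed scale with a linear
mixed model. For a block under test, the covariance of **y** is
`σ²_r rGRM + σ²_c cGRM + σ²_e I`; the null model drops the regional term. Both GRMs use
the standardized-dosage estimator with allele frequencies computed once on the full
analysis sample. That single-frequency convention is what makes the decomposition exact:
`(m_r·rGRM + m_c·cGRM)/(m_r+m_c)` equals the whole-genome GRM to machine precision, an
identity the test suite asserts at 1e-10 on every simulated dataset. Missing genotypes
are mean-imputed to 2p only inside GRM construction and association testing; the stored
panel keeps them missing.

REML maximization uses average-information (AI) updates with an EM first step and EM
fallback whenever an AI step fails to increase the restricted likelihood after step
halving. Components that would go negative are truncated at zero and excluded from the
AI solve while their gradient points outward (active set); convergence is declared at
|ΔlogL| < 1e-8 or 100 iterations, and non-convergence flags the result rather than
raising. The reported restricted log-likelihood includes the (n−p)·log 2π constant, and
standard errors come from the inverse AI matrix (delta method for variance fractions).
The residual variance is floored at ~1e-8 of the phenotypic variance to keep V positive
definite; a thresholded kinship matrix need not be positive semi-definite, so the
driver also shifts mass from the genetic components to the residual until the starting
V admits a Cholesky factorization.

Two computational kernels evaluate the same likelihood. The dense kernel works with
explicit n×n matrices and serves arbitrary GRM lists (e.g. cGRM + cGRM_kin in MLMA).
The rotated kernel expresses every matrix in the eigenbasis of one dense background
GRM, where the model covariance becomes diagonal plus a shared low-rank factor
U Uᵀ (U the standardized block dosages over √m_r); Woodbury identities then give the
solve, determinant, traces and AI terms in O(n·m²) per iteration. Scans and Monte-Carlo
studies pay one eigendecomposition per dataset and fit thousands of models through the
rotated kernel. A dedicated test checks the two kernels agree on the restricted
likelihood to 1e-8, and an optimization audit during development found the AI-REML
optimum within 2e-10 of a Nelder-Mead polish and within 1e-3 of a brute-force grid
(step 1e-3), which the acceptance suite re-runs.

In the two-GRM scan the per-block complement GRM is represented inside the whole-GRM
eigenbasis as `(m/m_c)·Λ_whole − (m_r/m_c)·U Uᵀ`, using the additivity identity, so the
whole-genome eigendecomposition is reused for every block. The preadjusted mode fits
one genome-wide GRM, forms `y* = y − X b̂ − û = σ̂²_e V⁻¹(y − X b̂)` (BLUP
residualization) and scans y* with a single-rGRM model per block against an
intercept-only null. With zero estimated genetic variance y* reduces to OLS residuals.
Preadjustment is deliberately the fast, conservative path; hits are re-tested with the
two-GRM model, which is the authoritative estimator.

## Boundary-mixture LRT and its finite-sample behaviour

Because σ²_r is tested on its boundary, p = 0.5·Pr(χ²₁ ≥ LRT) with p = 0.5 at LRT = 0.
The single-component version of this test is nominally calibrated in simulation
(rejection 0.0475 at α = 0.05 over 400 null replicates). The two-GRM version, where a
competing background component is estimated alongside, is measurably conservative at
n = 500 (rejection ≈ 0.02–0.03 for a binary K = 0.13 trait; ≈ 0.03–0.04 for Gaussian
phenotypes drawn exactly from the null law), approaching the nominal level slowly as n
grows. The optimizer audit above rules out an implementation cause: this is
finite-sample depletion of the boundary-mixture approximation, consistent with the
depletion of observed LRT statistics relative to expectation that regional-heritability
QQ plots show in practice. Tests of type-I error therefore probe a genuinely
conservative statistic at desk-scale n; users should read small-sample two-GRM
p-values as conservative.

## Scale transformations

Linear-scale effects on a 0/1 trait map to the logit scale by the first-order Taylor
factor 1/(P(1−P)); the SE scales identically, so Wald z and p are unchanged. Against a
logistic-regression oracle this recovers logORs within ~2.5% for |logOR| ≤ 0.3. The
constant is first-order only — published Taylor variants differ in higher-order terms,
so printed (OR, logOR) pairs from the literature are used in tests only as
exp/log-consistency checks, not as transformation ground truth. Observed-scale
heritabilities map to the liability scale by K²(1−K)²/(z²P(1−P)) (threshold t =
Φ⁻¹(1−K), z = φ(t)), reducing to K(1−K)/z² for a population sample; at K = P = 0.5 the
factor is π/2. The full round trip — threshold a liability with h² = 0.30 at K = 0.134,
estimate the observed-scale fraction by REML, transform back — recovers 0.30 within
Monte-Carlo error at n = 2000.

## Association and phasing

MLMA estimates variance components once under the null (no SNP term) and reuses the
resulting V for every SNP and haplotype in the block — the convention of the standard
mixed-model association tools, and O(tests) cheaper than per-SNP refits. Tests are Wald
tests from the GLS quadratic form; dosages enter as fixed effects after mean imputation.
Haplotypes are phased by an EM algorithm that enumerates, per distinct unphased
genotype, the 2^(h−1) compatible diplotype pairs (h heterozygous sites; blocks capped
at 25 SNPs, enumeration at 22 het sites — partition-ligation is not implemented) and
iterates frequencies to |Δf| < 1e-6. Expected dosages are posterior mean copy counts,
so each row sums to exactly 2; haplotypes with estimated frequency ≥ 0.01 are tested,
with Bonferroni adjustment over the number actually tested. Haplotype strings are
written in A1/A2 letters ordered by position.

## Blocks

Block coordinates are 1-based inclusive (a SNP at the end position is a member);
BED-style input is accepted via a flag. SNPs outside every interval become singleton
blocks or are dropped, per policy — both conventions exist in practice and the choice
is explicit. File-based blocks are the primary path so results are reproducible against
any block definition; `build_ld_blocks` additionally offers a D′ confidence-interval
partition (profile likelihood over |D′| with margins fixed at their MLEs, strong-LD at
CI ≥ (0.70, 0.98), recombination evidence below 0.9, greedy contiguous merging at 95%
strong pairs) as a self-contained stand-in for hotspot-based maps.

## Synthetic data

The generator emulates a family-plus-population cohort: per block, a pool of ≤ 2^m
distinct haplotypes with Dirichlet frequencies (within-block LD total along a
haplotype); founders draw two haplotypes per block, offspring inherit one intact block
haplotype per parent independently across blocks (recombination only at block
boundaries, so truth is exactly block-aligned); nuclear families of two founders plus
full sibs, the simplest structure producing the relatedness the method must absorb.
Liability is the sum of a regional component confined to one causal block, a polygenic
background over all other blocks, optional age/sex effects (age ~ U(18, 65), sex ~
Bernoulli(0.5), effects default 0 so genetic checks are unconfounded), and Gaussian
noise; cases are liabilities above Φ⁻¹(1−K). Ascertainment subsamples controls (or
cases) to a target case fraction, preserving the case genotype distribution.

Two effect-drawing conventions exist. `exact_scale=True` (default for dataset
emulation) rescales each genetic component so its sample variance equals the configured
fraction exactly — convenient when a dataset should realize its nominal design.
`exact_scale=False` draws per-SNP effects N(0, h²/m), which makes the phenotype law
exactly the Gaussian mixed model implied by the GRMs; all calibration and recovery
studies use this convention, because the rescaling conditions the data and visibly
depresses the null LRT. What the simulator does not emulate: realistic human LD maps
and allele-frequency spectra, multi-generation pedigrees (configurable family sizes but
nuclear only), genotyping error, X chromosome, selection. Passing tests therefore
establish the estimator's behaviour under its own model assumptions plus total
within-block LD, not performance on real LD structure.

## Study designs and problem sizes

Monte-Carlo suites fix a few gene-dropped panels and redraw phenotypes, paying one
background-GRM eigendecomposition per panel: null LRT calibration uses 10 panels × 100
replicates at n = 500 (100 nuclear families of 4 plus 100 unrelateds; 40 blocks × 12
SNPs; polygenic liability 0.25; K = 0.13); regional-variance recovery uses 4 panels ×
50 replicates at n = 2000 unrelateds (50 blocks × 10 SNPs; Gaussian phenotype with true
regional variance 0.05 and background 0.20 on the analysis scale); the liability round
trip uses 4 panels × 25 replicates at n = 2000 (h²_liab = 0.30, K = 0.134). The
acceptance script runs slightly smaller versions of the same designs. Recovery checks
compare the mean estimate to the truth within twice the empirical Monte-Carlo standard
error.

## Known limitations

- Two-GRM boundary LRT p-values are conservative at small n (see above).
- The preadjusted scan loses power when a block is a non-negligible fraction of the
  genotyped genome (the BLUP absorbs the regional signal); it is intended for block
  maps orders of magnitude larger than any single block.
- The Taylor logit transformation is first-order; exact correspondence with any
  particular published variant is not claimed.
- EM phasing assumes complete hard-call genotypes and unrelated-like random union of
  haplotypes; pedigree information is not used in phasing.
- The GREML power calculator takes the off-diagonal GRM variance as an input (default
  2e-5 for conventionally unrelated samples) and cannot reproduce a published power
  figure whose underlying h² and variance inputs are unknown.
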