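# Methods

## Model and estimators

The phenotype model throughout is the linear mixed model

    y = Xβ + Σ_i g_i + ε,   g_i ~ N(0, σ_i² A_i),   ε ~ N(0, σ_e² I),

with `X` an intercept plus covariates (age, sex, batch, water-arsenic
quartiles, smoking, BMI category — categorical covariates expanded to
indicators — and optionally 20 GRM principal components and/or major-locus
SNP dosages). The GRM estimator for samples j, k over SNPs i with
minor-allele dosage x and sample frequency p is

    A_jk = (1/m_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i)),
    A_jj = 1 + (1/m_jj) Σ_i [x_ij² − (1+2p_i)x_ij + 2p_i²] / (2p_i(1−p_i)),

with pairwise-complete missing handling (per-pair counts m) and
monomorphic SNPs skipped. Frequencies are always re-estimated on the
analysis sample, including after any subsetting. Three designs: the full
matrix; the thresholded matrix (off-diagonals < 0.05 → 0, diagonal kept,
strict inequality); and the greedily selected unrelated subset (repeatedly
drop the sample in the most ≥ 0.05 pairs, ties to the lexicographically
smallest id) with its GRM recomputed.

### REML

The restricted log-likelihood
`l_R = −½[log|V| + log|X'V⁻¹X| + y'Py]` is maximized with one EM step from
the start values (each component var(y)/(k+1)) followed by
average-information Newton steps, `AI_ij = ½ y'P A_i P A_j P y`, with
step-halving whenever a step would decrease `l_R`. Constrained fitting (the
default) floors components at 1e-6·var(y) and freezes a floored component
whose score pushes it further down; an unconstrained mode exists for
boundary diagnostics. Convergence: relative log-likelihood change < 1e-8
(unit tests tighten this when comparing against the brute-force oracle).
The component covariance is the inverse AI matrix at convergence; PVE
standard errors use the delta method. Component p-values are reported as
the boundary mixture LRT, p = ½ Pr(χ²₁ > 2Δl) (headline), and one-sided
Wald p-values are carried alongside. A GRM numerically equal to the
identity is rejected as aliased with the residual; the mixed-model
association path detects this case and degrades to generalized least
squares with V ∝ I (ordinary least squares).

### Two-component regional fits

The regional model `y = Xβ + g_region + g_genome + ε` is fitted for every
window. The genome-wide GRM (all SNPs, window included — the window's
double-counting biases the regional estimate conservatively) is
eigendecomposed once per scan; in that basis the genome component is
diagonal and the window component `Z_w Z_w'` (standardized window dosages,
scaled 1/√m_w) has rank ≤ m_w, so every Woodbury solve and trace in the
AI iteration is O(n·m_w). This is algebraically the same AI-REML as the
dense path — the equivalence is unit-tested — and makes a ~200-window scan
at n = 1,300 take seconds per replicate rather than hours. One numerical
subtlety: an orthogonal rotation preserves norms but not the sample mean,
so starting values and the constraint floor use the fixed-effect-residual
variance computed in the rotated basis, not `var(U'y)`.

Windows are built per chromosome with stride = size − overlap (defaults
100/50); a clipped trailing window is emitted only when it covers SNPs no
earlier window reached, and would be merged into its predecessor if
shorter than the overlap. The scan's LRT compares each two-component fit
to the genome-only model fitted once; significance uses 0.05 divided by
the realized number of tested windows.

### Association and scoring

Training betas for the polygenic model are per-SNP OLS coefficients given
the training covariates (residual regression, vectorized across SNPs;
missing dosages mean-imputed per SNP). Score-versus-outcome testing uses
the mixed model: variance components fitted once under the null, then GLS
per predictor with t-type Wald p-values — the binary outcome is analyzed
on the 0/1 scale. LD pruning is sliding-window greedy (window 50, step 5;
within a window the lower-MAF member of the worst r² > 0.2 pair is dropped,
ties against the later position). Region exclusion uses inclusive
closed bounds on position ± 1 Mb. Scores are mean weighted minor-allele
counts: the denominator is each individual's count of non-missing scored
SNPs. Scores are standardized to unit SD in the testing set, so sweep
betas are per SD of score; `OR = exp(β/(x(1−x)))` with x the testing-set
case proportion, CI bounds transformed from β ± 1.96·SE. A sweep refuses
any overlap between training and testing sample ids; thresholds passed by
zero SNPs yield an n_snps = 0 row with NaN statistics rather than aborting
the sweep (the per-call scoring function still raises, as its contract
states).

### Genotype QC and I/O

PLINK 1.9 bed/bim/fam (SNP-major) is read and written bit-exactly, with
dosages re-oriented on read so the counted allele is the minor allele in
the realized sample. QC order: sample call rate (< 0.97 excluded) first,
then SNP filters on the retained samples — call rate < 0.95, exact
two-sided Hardy–Weinberg p < 1e-10 (conditional exact test, no mid-p),
MAF < 0.01 — with allele orientation recomputed afterwards and every
exclusion reported with its reason. GRMs persist in the GCTA
`.grm.bin/.grm.N.bin/.grm.id` float32 triple.

## The synthetic cohort generator

The generator emulates the statistical structure the estimator contrasts
rely on, not human demography.

* **LD blocks.** Typed SNPs come in blocks (default length 50) drawn from a
  finite pool of 20 founder haplotypes per block; pool haplotypes are
  latent-AR(1) Gaussians (ρ = 0.95) thresholded at per-SNP frequencies
  U(0.05, 0.5), so adjacent-SNP r² decays within a block and is ~0 across
  blocks. Blocks are spread evenly over 22 autosomes, 5 kb SNP spacing.
* **Pedigree.** Families contribute full sibs via Mendelian transmission
  with free recombination at block boundaries (expected sib GRM 0.5); a
  configurable number of families also include a genotyped parent;
  unrelated singletons are founders.
* **Major locus.** One block on chromosome 10 carries a causal SNP
  (pool frequency ≈ 0.35) flanked by two named tag SNPs built from the
  causal column with one pool haplotype flipped (r² ≈ 0.75–0.9), so the
  two-tag fixed-effect adjustment removes most of the locus's PVE.
* **Rare untyped variants.** MAF U(0.001, 0.01) per founder haplotype,
  transmitted with their host block, withheld from the typed panel and
  recorded in the truth ledger. They contribute to sib resemblance (h²)
  but not to typed-SNP GRMs (h_g²) — the engine of the family-vs-unrelated
  contrast.
* **Phenotype.** DMA%-scale: mean 75, residual SD 8.5, clipped to
  [0.5, 99.5] ((three-sigma events; the clip negligibly perturbs realized
  fractions). Each genetic/environmental component is standardized
  in-sample and scaled to its target fraction of the *residual*
  (non-covariate) variance — so the REML estimand with covariates in X
  equals the target and realized fractions match targets almost exactly.
  Covariate effects follow the cohort's orientation (older age, female
  sex, lower water arsenic → higher DMA%) with magnitudes of ~0.1–3
  phenotype units; MMA%/iAs% split the remainder so species sum to 100.
  Shared environment is a sibship-level deviate only.
* **Outcome.** liability = −k·(standardized genetic value) + noise
  (k = 0.6 by default), cases are the top case_fraction (default 0.61,
  matching a 2,014/1,285 case-control mix), so DMA%-raising alleles are
  protective.

Default cohort conditions: 700 sib-pair families (50 with a genotyped
parent) + 600 singletons ≈ 2,050 samples, 20k typed SNPs, 300 rare untyped
variants, variance fractions 0.07 (major) / 0.08 (polygenic, 500 causal
SNPs) / 0.30 (rare) / 0.15 (shared environment).

What the generator does *not* emulate: realistic recombination maps or
allele-frequency spectra, genotyping error and missingness patterns,
imputation, population stratification (available separately in tests via
frequency-diverged subpopulations), or ascertainment. Passing tests
therefore demonstrate estimator correctness and the qualitative
architecture contrasts, not cohort-specific point estimates.

## Validation problem sizes

The validation suite runs the estimators at desk scale, chosen so the
relevant signal-to-noise regimes are preserved:

* Oracle agreement: 25 datasets, n ≤ 200, AI-REML vs an independent
  profile-likelihood grid/golden-section maximizer, 1e-3 per component.
* Recovery: 100 cohorts, n = 800 (280 sib-pair families + 240 singletons),
  6,000 SNPs in 5-SNP blocks, true common-SNP h² 0.15.
* Architecture contrast: 20 cohorts, n = 1,000, typed common 0.15 + rare
  untyped 0.40; 3-SNP blocks keep GRM noise below the 0.05 cutoff so the
  unrelated subset stays large.
* Regional power: 20 cohorts, n = 1,300 unrelated, 10,050 SNPs,
  ~180 windows, planted 7% locus over an 0.10 polygenic background.
* Null calibration: 400 permutation REML fits and 1,000 null-SNP
  mixed-model tests.
* Sweep trend: 100 cohorts, 600/600 train/test, polygenic 0.30 with 500
  causal SNPs and liability weight 0.7.

Block length is the lever that trades LD realism against GRM noise: the
off-diagonal GRM noise SD scales with (number of blocks)^(−1/2), so
configurations that exercise the 0.05 relatedness cutoff use many short
blocks, while LD-pruning and regional tests use longer blocks.

## Known limitations

* The unrelated-subset GREML estimate is intrinsically noisy below a few
  hundred samples (SE ≳ 0.1); the pipeline reports it with its SE rather
  than suppressing it, mirroring the analysis design it reproduces.
* The boundary-mixture LRT is asymptotic; at n of a few hundred it is
  mildly conservative (observed null rejection ≈ 0.045–0.05 at nominal
  0.05).
* Mixed-model association of SNPs that also feed the GRM is subject to the
  usual proximal-contamination power loss; no leave-one-chromosome-out
  GRM is implemented.
* Binary outcomes use the linear mixed model on the 0/1 scale (by design);
  no liability-scale transformation of score-association effect sizes is
  attempted beyond the OR conversion.
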