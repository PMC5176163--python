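# Methods

This note documents the statistical model the package implements, the
synthetic-data generator's assumptions, the numerical choices, and what the
test suite does and does not establish.

## 1. Phenotype construction

Blood pressure enters the analysis as the mean of the last two of three
resting readings (the first reading is systematically elevated and is
discarded). Antihypertensive treatment is handled by *adding* a fixed offset
to treated individuals' readings — +10 mmHg systolic, +5 mmHg diastolic —
rather than by a treatment covariate; this is the standard censored-outcome
adjustment and is more powerful than modelling treatment as a regressor. The
adjusted values `sbp_adj`/`dbp_adj` are the responses everywhere downstream.

## 2. QC

SNPs are retained iff MAF > 1%, call rate > 95% and exact HWE p > 0.001, all
*strict* inequalities (a SNP at exactly MAF 0.01 is removed). MAF is computed
over non-missing calls only. The HWE test is the standard exact test
conditioning on allele counts: the p-value is the sum of probabilities of all
heterozygote counts no more probable than the one observed, computed in log
space from the hypergeometric-type conditional distribution. A mid-p variant
(`hwe_midp`) subtracts half the observed configuration's probability; it is
off by default.

## 3. Relatedness

KING-robust between-family kinship: for a pair (i, j) over pairwise-complete
SNPs, φ = (N_het,het − 2·N_opposite-homozygote) / (N_het(i) + N_het(j)).
Negative values are legitimate (pairs of different ancestral backgrounds);
duplicated genotypes give exactly 0.5. Pairs sharing < 100 informative SNPs
are flagged low-confidence.

PC-AiR is implemented as a deterministic simplification of the published
procedure: (1) a maximal set with all pairwise kinship < 0.025 is built by
repeatedly removing the individual with the most remaining relatives (ties
broken by ID sort order); (2) PCA (SVD) of the unrelated set's genotypes,
mean-centred at 2p̂ and scaled by √(2p̂(1−p̂)), missing values imputed to the
SNP mean; (3) relatives are projected onto the unrelated-set loadings. The top
10 scores join the covariate block of every regression. PC signs are fixed by
making each component's largest-magnitude loading positive.

A caveat measured during development: the kinship estimator's sampling noise
at toy SNP counts (sd ≈ 0.011 at 8,000 SNPs) pushes a nontrivial fraction of
truly unrelated pairs over the 0.025 threshold, so partitions resembling a
real cohort's (≈120 unrelated / 37 related of 157) only appear at realistic
marker counts (≳25k SNPs). Tests therefore assert the partition *logic*, not
a particular split.

## 4. Frequentist scans and thresholds

Both scans are OLS with the fixed covariate block (global ancestry, sex, age,
education, BMI, PC1–10) and a per-SNP focal term: the 0/1/2 local-ancestry
code (admixture mapping) or the 0/1/2 genotype (association mapping).
Genome-wide fits use Frisch–Waugh–Lovell residualisation against the shared
covariate block, which is algebraically identical to the full per-SNP OLS and
vectorises across SNPs; SNPs with missing genotypes fall back to a per-SNP
complete-case fit. Wald p-values use the t distribution with n − k df by
default (n is small); a normal-reference option exists for compatibility with
other implementations.

The admixture testing burden T_adm is the mean per-individual count of
adjacent-SNP local-ancestry changes, summed over autosomes. Whether a
switch-free chromosome should still count one test is not decidable from the
counting rule's plain wording; the default mode `switches` counts only
switches, and `switches_plus_chrom` adds one per chromosome. The association
burden T_assoc is the post-QC SNP count. Bonferroni thresholds are
−log₁₀(α/T); at the reference scales α = 0.05, T_adm = 78.82 and
T_assoc = 27,559 these are 3.2 and 5.74. (A published description of the
association threshold elsewhere states 1/27,559 = 3.6×10⁻⁵; the
−log₁₀(0.05/27,559) = 5.74 form is the one implemented, since it is the one
the threshold-setting procedure defines.)

## 5. The joint Bayesian statistic

The source analysis describes the chaining — admixture posteriors as
association priors with partial Bonferroni correction — without printing the
Bayes algebra, so the package commits to an explicit reconstruction and
exposes every piece:

* **Approximate Bayes factor.** Wakefield-style, from (β̂, se) alone:
  ABF = √(se²/(se²+W)) · exp(z²W/(2(se²+W))), oriented so ABF > 1 favours
  association. W = (`prior_effect_sd` · SD(y))² with `prior_effect_sd` = 0.2:
  a plausible signal shifts the phenotype by a fifth of a phenotypic SD
  (≈ 4 mmHg systolic). W = 0 degenerates to ABF = 1.
* **Stage-A prior.** π₀ = 1/T_adm (`pi_mode="one_over_t_adm"`): one expected
  signal per effective admixture test. The alternative `alpha_over_t_adm`
  (0.05/T_adm) is configurable.
* **Partial Bonferroni.** π_assoc = P_adm / (T_assoc/T_adm), i.e. the
  admixture posterior is discounted by the *residual* per-block SNP burden
  rather than the full SNP count; clipped to [10⁻¹², 1−10⁻¹²] to keep odds
  finite.
* **Stage-B evidence.** Within each local-ancestry stratum (0/1/2 copies) the
  model is fitted by OLS — Model 1: BP ~ SNP + covariates; Model 2: + UT;
  Model 3: + UT + SNP×UT with the interaction as the focal term — and stratum
  estimates are pooled by inverse-variance-weighted fixed effects
  (w = 1/se², β = Σwβ/Σw, se = (Σw)^(−1/2)). Strata are dropped when smaller
  than `min_stratum_n` = 10, when the focal term has no variance, or when the
  stratum design is collinear or lacks residual df; a SNP with no
  contributing stratum is excluded with the reason recorded (this mirrors the
  exclusion of SNPs whose genotypes lose all variance once stratified by
  ancestry). When every individual falls in one stratum the stratified fit
  reduces exactly to the unstratified fit.
* **Decision rule.** joint posterior = π_assoc·ABF odds-combined; significant
  iff ≥ 0.5 (exactly; the 0.5-posterior boundary corresponds to
  ABF = (1−π)/π).

Within ancestry strata the local-ancestry regressor is constant, so the
stratified regressions use the SNP (or interaction) as the focal term — the
only non-degenerate reading of the stratify-then-recombine description.

These reconstructions are design choices, not claims about the exact
published algebra; tests of the Bayesian layer are accordingly closed-form
and property-based (monotonicity in |z| and in P_adm, scale invariance,
threshold identity, null calibration) rather than comparisons with any
published per-SNP posterior.

Model 3 additionally filters to MAF > 10% (strict) so that minor-allele
homozygotes exist at both exposure levels. UT dichotomisations: No/Yes splits
at ≥1 affirmative response; Low/High at ≥3 — the threshold motivated by the
weathering hypothesis (cumulative psychosocial stress must pass a threshold
before manifesting physiologically).

## 6. Permutation confirmation

Hits (posterior ≥ 0.5) are re-tested by shuffling the phenotype block — BP,
medication flag, age, sex, education, BMI, UT — as one unit against the fixed
genotype/ancestry data, recomputing the *full* joint statistic (admixture
prior included) per permutation, and counting permutations that reach 0.5.
Confirmation requires count ≤ ⌊α·n_perm⌋ (500 at 10,000/0.05). Defaults:
n_perm = 10,000, master seed 385, per-permutation substreams keyed by
(seed, index) so results are independent of evaluation order; index 0 is the
identity permutation by construction.

Two deliberate deviations from a literal shuffle-all-covariates reading:
global ancestry and the PC scores stay in the *fixed* block, because they are
deterministic functions of the genotypes — shuffling them against the
genotypes they were computed from would not produce the intended null.
`literal_covariate_shuffle=True` restores the literal behaviour. Whether the
admixture prior should be recomputed per permutation is also not fully
specified; the default recomputes it (the full statistic), and
`recompute_prior=False` reuses the observed prior.

## 7. The synthetic cohort

The generator's defaults are the stated conditions of the cohort the pipeline
targets, not tuning knobs: 157 individuals (120 founders + 37 gamete-dropped
relatives), two-way admixture with α = 0.8 target (African) ancestry and 7
generations, ~27.6k SNPs scalable down, covariates matched to the published
summary table (age ≈ 41 ± 12 truncated to the 25–65 sampling frame, 68%
female, education ≈ 13.2 ± 2.4 y, BMI ≈ 32.4 ± 9.4), UT counts Poisson with
means 1.62/1.48 truncated to 0–9, ≈30% medicated.

* **Ancestral frequencies.** Balding–Nichols around a base frequency
  p₀ ~ U(0.05, 0.95): p₁, p₂ ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) independently,
  F = 0.15 by default (continental-scale differentiation), clipped to
  [0.01, 0.99]. Under the construction E[(p₁−p₂)²/(p₀(1−p₀))] = 2F, which the
  tests verify by Monte Carlo.
* **Ancestry tracks.** Per haplotype and chromosome, breakpoints follow a
  Poisson process at `generations` per Morgan and each segment's ancestry is
  i.i.d. Bernoulli(α) — the simplest process consistent with a
  generations/α parameterisation (a Markov model with explicit transition
  matrix would differ only in segment-length autocorrelation). The expected
  diploid switch count is ≈ 2·L·g·2α(1−α) for genome length L; at the default
  L ≈ 35.6 M and g = 7 this is ≈ 160 — larger than a real LAMP-derived burden
  (≈ 79), because smoothed HMM output and coarser marker spacing hide
  back-to-back switches. The marker grid can only *hide* switches, hence the
  asymmetric tolerance in the corresponding test.
* **Genotypes.** Each haploid allele is Bernoulli(frequency of its ancestral
  population at that SNP); genotype = allele sum; missingness is MCAR at 1%
  (no mechanism was stated; MCAR is the neutral choice).
* **Relatives.** Children are produced by gamete-dropping: each parent
  transmits one recombined haplotype (crossovers Poisson at 1 per Morgan per
  meiosis — the biological rate for a single meiosis), carrying ancestry and
  allele states together. Expected KING kinship for parent-offspring pairs is
  ≈ 0.25.
* **Phenotypes.** Exactly linear: intercept + covariate effects + planted
  SNP/ancestry/UT/interaction effects + N(0, σ) noise, on the adjusted-BP
  scale (systolic defaults: intercept 101.7, +0.45/y age, −4 female,
  −0.3/y education, +0.55/unit BMI, σ = 15; diastolic scaled accordingly).
  The medication flag is logistic in the *noise-free* latent systolic value
  (centre 140 mmHg, scale 8 mmHg; calibrated once to ≈30% treated, matching
  48/157, then frozen), and raw readings subtract the offset from medicated
  rows so the pipeline's adjustment step round-trips exactly.
* **Seeding.** All stages draw from substreams of a single master seed
  (SeedSequence spawn keys per stage); the canonical permutation seed 385 is
  the default only in the permutation module.

What the generator does **not** emulate: background linkage disequilibrium
beyond ancestry-block structure, realistic allele-frequency spectra or marker
spacing, genotyping-error mechanisms, assortative mating, or any particular
real locus. A green simulation test therefore establishes that the estimator
recovers the generative model it assumes — not that it would behave
identically on array data with LD.

## 8. Numerical choices

* Rank checks via column-pivoted QR with tolerance max|R_ii|·max(n,k)·10⁻¹⁰;
  rank-deficient designs raise with the offending columns named.
* Focal columns with variance ≤ 10⁻¹² are excluded as "constant";
  residualised focal columns with negligible remaining sum of squares as
  "collinear".
* ABF computed in log space; log-ABF > 700 returns +inf and the posterior
  saturates at 1.
* Sex is coded 0 = male / 1 = female; reported effects are
  reference-dependent.
* Reported posteriors in the significant-hits table are formatted to two
  decimals and capped at 1.00.
* VCF coordinates are 1-based; half-calls become missing; non-biallelic and
  non-autosomal records are skipped with a logged reason.

## 9. Known limitations

* Relatedness is handled through PC covariates exactly as in the target
  analysis — no mixed model / GRM. With close relatives this undercorrects
  the association test's effective sample size.
* The partial-Bonferroni algebra is a reconstruction (Section 5); absolute
  posterior values depend on `prior_effect_sd` and `pi_mode`, and only their
  calibration and ordering properties are tested.
* The stratified Model 3 fit needs minor-allele homozygotes within strata and
  exposure levels; at n ≈ 157 many SNPs are legitimately excluded, as the
  MAF > 10% filter anticipates.
* The permutation stage recomputes the full statistic per permutation and is
  O(n_perm × hits); the default budget guard refuses runs beyond ~2×10⁷
  evaluations.
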