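# admixjoint

Joint Bayesian admixture-and-association mapping for quantitative traits in
recently admixed cohorts, with a synthetic-cohort generator, frequentist
genome scans, gene-by-environment interaction models, and permutation-based
false-positive confirmation.

## The problem

In a recently admixed population (e.g. African Americans, ~80% African / 20%
European ancestry mixed over ~7 generations), chromosomes are mosaics of long
ancestry blocks. **Admixture mapping** regresses a trait on the *local
ancestry* code (0/1/2 copies of African ancestry at a locus) and pays a
multiple-testing price proportional to the number of ancestry *switch points*
per genome (order 10²), not the number of SNPs (order 10⁴–10⁶). **Association
mapping** regresses the trait on the genotype itself and pays the full SNP
burden. With a small cohort (n ≈ 157) neither scan alone has power at its
Bonferroni threshold.

The joint method chains the two so the cheap scan buys prior mass for the
expensive one:

1. **Stage A.** The admixture-mapping estimate (β̂_adm, se_adm) at each SNP is
   converted to an approximate Bayes factor

   ABF = √(se² / (se² + W)) · exp(z²·W / (2(se² + W))),  z = β̂/se,

   with prior effect variance W = (0.2·SD(y))², and combined with the prior
   π₀ = 1/T_adm (one expected signal per effective admixture test) to give the
   admixture posterior P_adm.

2. **Stage B (partial Bonferroni).** The association prior is
   π_assoc = P_adm / (T_assoc/T_adm) — the admixture posterior discounted only
   by the residual per-block SNP burden. The association evidence is the
   inverse-variance-weighted combination of genotype effects fitted *within*
   each local-ancestry stratum; its ABF times the prior odds gives the **joint
   posterior probability**. A SNP is significant when that posterior ≥ 0.5.

Three progressive models are supported: Model 1 (SNP), Model 2 (SNP plus an
unfair-treatment exposure count UT-Self or UT-Other, 0–9), Model 3 (SNP×UT
interaction as the focal term, UT dichotomised No/Yes at ≥1 or Low/High at ≥3,
with a strict MAF > 10% filter). Every hit is confirmed by permutation:
phenotype + covariates shuffled as a block against fixed genotypes/ancestry,
the full statistic recomputed; a hit is confirmed when at most
⌊α·n_perm⌋ permutations (500 of 10,000 at α = 0.05) reach posterior 0.5.

Supporting machinery: array QC (MAF > 1%, call rate > 95%, exact HWE p >
0.001, all strict), medication-adjusted blood pressure (+10 mmHg SBP / +5 mmHg
DBP for treated individuals), KING-robust kinship, simplified PC-AiR
(maximal-unrelated-set PCA with projection of relatives), and a
Balding–Nichols + Poisson-ancestry-track cohort simulator with gamete-dropped
relatives and known ground truth.

## Worked example

Simulate a study-scale cohort (157 individuals, 37 relatives, 2,000 SNPs)
with one ancestry-supported causal SNP for systolic BP (+9 mmHg per allele at
the most African-differentiated marker, +4 mmHg per ancestry copy), then run
the full pipeline:

```python
import numpy as np
from admixjoint import (CohortSimulator, PipelineConfig, run_pipeline,
                        simulate_ancestral_frequencies)
from admixjoint.sim import PhenotypeModel

seed, n_snps = 7, 2000
freqs = simulate_ancestral_frequencies(n_snps, fst=0.15, seed=seed)
causal = int(np.argmax(freqs.freq_pop1 - freqs.freq_pop2))
sim = CohortSimulator(n_ind=157, n_snps=n_snps, n_related=37, seed=seed,
                      sbp_model=PhenotypeModel(causal_snps={causal: 9.0},
                                               causal_ancestry={causal: 4.0},
                                               noise_sd=12.0))
cohort = sim.simulate()
cfg = PipelineConfig(models=[(1, None, "count")], response="sbp", n_perm=1000,
                     out_dir="demo_out")
res = run_pipeline(cfg, data=dict(genotypes=cohort.genotypes, snps=cohort.snps,
                                  local_ancestry=cohort.local_ancestry,
                                  samples=cohort.samples))
print("\n".join(res.log))
```

prints

```
loaded 157 individuals x 2000 SNPs
QC: 1961/2000 SNPs pass (maf fail 37, call fail 1, hwe fail 1)
effective tests: t_adm=134.02, t_assoc=1961
PC-AiR: 69 unrelated / 88 related at kinship >= 0.025
admixture scan (sbp): 14 hits above -log10 threshold 3.43, 0 excluded
association scan (sbp): 1 hits above -log10 threshold 4.59, 0 excluded
joint model 1 (sbp, ut=None/count): 1 hits, 0 SNPs excluded
permutation (sbp model 1): 1/1 hits confirmed
```

Reading it: QC removed 39 of 2,000 SNPs. The effective admixture burden is
134 switch-derived tests versus 1,961 SNP tests, so the admixture threshold
(−log₁₀ p = 3.43) is far more lenient than the association one (4.59). The
whole ancestry block around the causal locus clears the admixture threshold
(14 SNPs). At the causal SNP the joint machinery gives

```
adm_posterior      1.0        # stage A: ancestry evidence saturates the prior
assoc_prior        0.068      # after the partial-Bonferroni discount (1961/134)
combined_beta      8.59       # IVW genotype effect across ancestry strata (truth: 9)
combined_se        2.33
assoc_abf          48.6
joint_posterior    0.78       # >= 0.5 -> significant
```

and the permutation stage confirms it — 0 of 1,000 phenotype-shuffled
replicates reach posterior 0.5 (threshold 50):

```
           model  n_perm  exceed_count  threshold_count  confirmed
snp000708      1    1000             0               50       True
```

`demo_out/` then contains the QC report, kinship and PC tables, per-SNP scan
and joint TSVs, Manhattan tables, and `significant_hits.tsv`.

The same run works from the shell: `admixjoint simulate --seed 7 --n-ind 157
--n-snps 2000 --out data/` followed by `admixjoint all --config cfg.yaml`.

## Acceptance script

`scripts/acceptance.py` re-runs the complete analysis from scratch on the
default synthetic world — simulation, QC, ancestry/kinship/PCs, both
frequentist scans, joint Models 1–3 for SBP and DBP, and permutation
confirmation of every hit — and writes its summary JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `admixjoint.sim` — synthetic cohorts (Balding–Nichols frequencies, Poisson
  ancestry tracks, gamete-dropped relatives, covariates/UT, phenotypes)
- `admixjoint.io` — VCF/TSV genotype I/O, BP construction, QC
- `admixjoint.ancestry` — global ancestry, switch counting, KING, PC-AiR
- `admixjoint.scan` — OLS engine, admixture/association scans, thresholds
- `admixjoint.joint` — ABF, priors, stratified IVW, Models 1–3
- `admixjoint.permutation` — shuffling plan and confirmation rule
- `admixjoint.pipeline`, `admixjoint.cli` — orchestration, reports, CLI

See `docs/methods.md` for the model details, simulator assumptions, numerical
choices and known limitations.
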