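"""Synthetic admixed-cohort generator with known ground truth.

The generator emulates the statistical structure a joint admixture-and-
association analysis assumes, for a two-way admixed population (target
ancestry "pop1", e.g. African; other ancestry "pop2", e.g. European):

* ancestral allele frequencies from a Balding–Nichols construction around a
  common base frequency, with differentiation ``fst``;
* haploid local-ancestry tracks with Poisson breakpoints at a rate of
  ``generations`` per Morgan and segment ancestries drawn i.i.d.
  Bernoulli(``alpha``) — the simplest process consistent with a
  generations/alpha admixture parameterisation;
* genotypes drawn per haplotype from the allele frequency of that
  haplotype's ancestral population at the SNP;
* relatives built by gamete-dropping from founder haplotypes;
* covariates, unfair-treatment (UT) counts and blood-pressure phenotypes on
  the scale of the cohort the pipeline targets (n = 157, ≈80/20 admixture,
  7 generations, ≈30% medicated).

Default cohort parameters are the stated study conditions; they are not knobs
to tune for test outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import write_genotypes_tsv, write_genotypes_vcf, write_samples

__all__ = [
    "DEFAULT_CHROM_LENGTHS",
    "AncestralModel",
    "AdmixtureParams",
    "PhenotypeModel",
    "SimulatedCohort",
    "simulate_ancestral_frequencies",
    "simulate_local_ancestry",
    "simulate_genotypes",
    "simulate_relatives",
    "simulate_covariates_ut",
    "simulate_phenotype",
    "CohortSimulator",
    "write_cohort",
]

#: Approximate sex-averaged genetic lengths of the 22 autosomes, in Morgans.
DEFAULT_CHROM_LENGTHS = (
    2.86, 2.69, 2.23, 2.14, 2.04, 1.92, 1.87, 1.70, 1.68, 1.81, 1.58,
    1.75, 1.26, 1.20, 1.42, 1.35, 1.29, 1.19, 1.08, 1.08, 0.62, 0.74,
)

FREQ_EPS = 0.01  # allele frequencies clipped to [FREQ_EPS, 1 - FREQ_EPS]


def _rng(seed, *stage) -> np.random.Generator:
    """Stage-keyed substream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *stage]))


@dataclass
class AncestralModel:
    """Marker map and ancestral allele frequencies of the two source populations."""

    n_snps: int
    chrom_lengths: tuple
    snp_chrom: np.ndarray       # 1-based chromosome per SNP
    snp_positions: np.ndarray   # genetic position in Morgans within chromosome
    freq_pop1: np.ndarray       # target-ancestry allele frequencies
    freq_pop2: np.ndarray
    fst: float

    def __post_init__(self):
        for f in (self.freq_pop1, self.freq_pop2):
            if len(f) != self.n_snps:
                raise ValueError("frequency vector length != n_snps")
            if np.any((f <= 0) | (f >= 1)):
                raise ValueError("allele frequencies must lie strictly in (0,1)")
        for c in np.unique(self.snp_chrom):
            if np.any(np.diff(self.snp_positions[self.snp_chrom == c]) < 0):
                raise ValueError(f"positions not monotone on chromosome {c}")

    @property
    def snp_ids(self):
        return pd.Index([f"snp{i:06d}" for i in range(self.n_snps)], name="snp_id")

    def snp_table(self) -> pd.DataFrame:
        """SNP annotation table with bp positions at 1 cM/Mb."""
        return pd.DataFrame(
            {
                "chrom": self.snp_chrom.astype(int),
                "pos": np.round(self.snp_positions * 1e8).astype(int) + 1,
                "ref": "A",
                "alt": "G",
            },
            index=self.snp_ids,
        )


@dataclass
class AdmixtureParams:
    """Admixture process parameters (defaults: 0.8 target ancestry, 7 generations)."""

    alpha: float = 0.8
    generations: int = 7
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0 or self.alpha in (0.0, 1.0)):
            raise ValueError("alpha must lie in [0,1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class PhenotypeModel:
    """Linear generative model for one blood-pressure response (mmHg).

    Defaults reproduce the systolic scale of the target cohort (mean ≈ 131
    mmHg adjusted, SD ≈ 20): intercept plus age/sex/education/BMI effects,
    normal noise, and optional causal SNP / local-ancestry / UT /
    SNP×UT-interaction effects with indices into the simulated SNP panel.
    """

    intercept: float = 101.7
    beta_age: float = 0.45
    beta_sex: float = -4.0        # sex coded 0=male, 1=female
    beta_edu: float = -0.3
    beta_bmi: float = 0.55
    beta_globalanc: float = 0.0
    beta_ut_self: float = 0.0
    beta_ut_other: float = 0.0
    noise_sd: float = 15.0
    causal_snps: dict = field(default_factory=dict)       # snp index -> mmHg/allele
    causal_ancestry: dict = field(default_factory=dict)   # snp index -> mmHg/copy
    # (snp index, ut variable, ut coding) -> mmHg per allele×UT-level
    interactions: dict = field(default_factory=dict)
    med_center: float = 140.0     # logistic medication model on the latent BP
    med_scale: float = 8.0
    med_offset: float = 10.0      # mmHg removed from raw readings of medicated rows

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def dbp_default_model() -> PhenotypeModel:
    """Diastolic-scale defaults (mean ≈ 83 mmHg adjusted, SD ≈ 14)."""
    return PhenotypeModel(intercept=69.0, beta_age=0.2, beta_sex=-2.0,
                          beta_edu=-0.2, beta_bmi=0.3, noise_sd=12.0,
                          med_offset=5.0)


@dataclass
class SimulatedCohort:
    """A generated cohort: data matrices, sample table, and the ground truth."""

    genotypes: pd.DataFrame
    local_ancestry: pd.DataFrame
    samples: pd.DataFrame
    snps: pd.DataFrame
    truth: dict
    pedigree: list
    hap_ancestry: np.ndarray = field(default=None, repr=False)  # (n, 2, m) uint8
    hap_alleles: np.ndarray = field(default=None, repr=False)   # (n, 2, m) uint8
    model: AncestralModel = field(default=None, repr=False)
    params: AdmixtureParams = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------

def simulate_ancestral_frequencies(
    n_snps: int, fst: float = 0.15, base_freq_range=(0.05, 0.95),
    seed: int = 0, chrom_lengths=DEFAULT_CHROM_LENGTHS,
) -> AncestralModel:
    """Balding–Nichols allele frequencies and a uniform marker map.

    Each SNP gets a base frequency p0 ~ Uniform(base_freq_range); the two
    population frequencies are independent Beta(p0 (1-F)/F, (1-p0)(1-F)/F)
    draws (identical to p0 when F = 0), clipped to [0.01, 0.99].  SNPs are
    assigned to chromosomes in proportion to genetic length, with sorted
    uniform positions.
    """
    if not (0.0 <= fst < 1.0):
        raise ValueError(f"fst must lie in [0,1), got {fst}")
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    rng = _rng(seed, 1)
    lengths = np.asarray(chrom_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    p0 = rng.uniform(*base_freq_range, size=n_snps)
    if fst == 0.0:
        p1 = p0.copy()
        p2 = p0.copy()
    else:
        a = p0 * (1.0 - fst) / fst
        b = (1.0 - p0) * (1.0 - fst) / fst
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    p1 = np.clip(p1, FREQ_EPS, 1.0 - FREQ_EPS)
    p2 = np.clip(p2, FREQ_EPS, 1.0 - FREQ_EPS)
    # allocate SNPs to chromosomes proportionally to genetic length
    share = lengths / lengths.sum()
    counts = np.floor(share * n_snps).astype(int)
    counts[: n_snps - counts.sum()] += 1
    chrom = np.repeat(np.arange(1, len(lengths) + 1), counts)
    pos = np.concatenate(
        [np.sort(rng.uniform(0.0, lengths[c - 1], size=n)) for c, n in
         zip(range(1, len(lengths) + 1), counts)]
    )
    return AncestralModel(
        n_snps=n_snps, chrom_lengths=tuple(lengths), snp_chrom=chrom,
        snp_positions=pos, freq_pop1=p1, freq_pop2=p2, fst=fst,
    )


def _haploid_tracks(model: AncestralModel, alpha: float, generations: int,
                    n_hap: int, rng: np.random.Generator) -> np.ndarray:
    """(n_hap, n_snps) uint8 matrix of target-ancestry indicators."""
    out = np.empty((n_hap, model.n_snps), dtype=np.uint8)
    lengths = np.asarray(model.chrom_lengths)
    for c in np.unique(model.snp_chrom):
        sel = model.snp_chrom == c
        pos = model.snp_positions[sel]
        L = lengths[c - 1]
        if pos.size == 0:
            raise ValueError(f"chromosome {c} has no SNPs")
        for h in range(n_hap):
            n_bp = rng.poisson(generations * L)
            bps = np.sort(rng.uniform(0.0, L, size=n_bp))
            states = (rng.random(n_bp + 1) < alpha).astype(np.uint8)
            out[h, sel] = states[np.searchsorted(bps, pos, side="right")]
    return out


def simulate_local_ancestry(model: AncestralModel, params: AdmixtureParams,
                            n_ind: int, seed: int | None = None):
    """Diploid local-ancestry matrix plus the underlying haploid tracks.

    Returns ``(local, haps)`` where ``local`` is an individuals × SNPs
    DataFrame of 0/1/2 target-ancestry copies and ``haps`` the (n, 2, m)
    haploid indicator array the pipeline never sees but the genotype and
    gamete-dropping stages require.
    """
    rng = _rng(params.seed if seed is None else seed, 2)
    haps = _haploid_tracks(model, params.alpha, params.generations, 2 * n_ind, rng)
    haps = haps.reshape(n_ind, 2, model.n_snps)
    local = pd.DataFrame(
        haps.sum(axis=1),
        index=pd.Index([f"ind{i:04d}" for i in range(n_ind)], name="individual_id"),
        columns=model.snp_ids,
    )
    return local, haps


def simulate_genotypes(model: AncestralModel, hap_ancestry: np.ndarray,
                       seed: int = 0, missing_rate: float = 0.01,
                       individual_ids=None):
    """Genotypes from haploid ancestry tracks.

    Each haploid allele is Bernoulli with the frequency of its ancestral
    population at that SNP; the genotype is the allele sum, with optional
    missing-completely-at-random masking.  Returns ``(genotypes, hap_alleles)``.
    """
    if hap_ancestry.shape[-1] != model.n_snps:
        raise ValueError("ancestry/model SNP count mismatch")
    rng = _rng(seed, 3)
    n_ind = hap_ancestry.shape[0]
    freqs = np.where(hap_ancestry == 1, model.freq_pop1, model.freq_pop2)
    alleles = (rng.random(freqs.shape) < freqs).astype(np.uint8)
    geno = alleles.sum(axis=1).astype(float)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = np.nan
    ids = (pd.Index(individual_ids, name="individual_id") if individual_ids is not None
           else pd.Index([f"ind{i:04d}" for i in range(n_ind)], name="individual_id"))
    genotypes = pd.DataFrame(geno, index=ids, columns=model.snp_ids)
    return genotypes, alleles


def _gamete(hap_pair: np.ndarray, model: AncestralModel,
            rng: np.random.Generator) -> np.ndarray:
    """One transmitted haplotype: recombine a parent's two haplotypes.

    Crossovers follow a Poisson process of rate 1 per Morgan per meiosis.
    """
    child = np.empty(model.n_snps, dtype=np.uint8)
    lengths = np.asarray(model.chrom_lengths)
    for c in np.unique(model.snp_chrom):
        sel = model.snp_chrom == c
        pos = model.snp_positions[sel]
        L = lengths[c - 1]
        n_x = rng.poisson(L)
        xs = np.sort(rng.uniform(0.0, L, size=n_x))
        start = rng.integers(0, 2)
        which = (start + np.searchsorted(xs, pos, side="right")) % 2
        seg = hap_pair[:, sel]
        child[sel] = seg[which, np.arange(pos.size)]
    return child


def simulate_relatives(cohort: SimulatedCohort, n_parent_offspring: int = 0,
                       n_sibs: int = 0, seed: int = 0,
                       missing_rate: float = 0.01) -> SimulatedCohort:
    """Append gamete-dropped relatives to a founder cohort.

    ``n_parent_offspring`` children are produced from distinct random founder
    pairs (each child is parent-offspring related to two founders);
    ``n_sibs`` additional children are full siblings of the first
    ``n_sibs`` of those children (same parent pair).  The pedigree is
    recorded as (child, parent1, parent2) triples.
    """
    n_children = n_parent_offspring + n_sibs
    if n_children == 0:
        return cohort
    model = cohort.model
    rng = _rng(seed, 4)
    founders = list(cohort.genotypes.index)
    if 2 * n_parent_offspring > len(founders):
        raise ValueError("requested relatives exceed available founders")
    if n_sibs > n_parent_offspring:
        raise ValueError("each sib pair needs an existing parent pair")
    perm = rng.permutation(len(founders))
    pairs = [(founders[perm[2 * i]], founders[perm[2 * i + 1]])
             for i in range(n_parent_offspring)]
    pairs += [pairs[i] for i in range(n_sibs)]
    pos = {ind: i for i, ind in enumerate(founders)}
    new_anc, new_all, ped, child_ids = [], [], [], []
    for k, (p1, p2) in enumerate(pairs):
        cid = f"rel{k:04d}"
        anc = np.empty((2, model.n_snps), dtype=np.uint8)
        alle = np.empty((2, model.n_snps), dtype=np.uint8)
        for s, parent in enumerate((p1, p2)):
            i = pos[parent]
            # transmit ancestry and alleles through the same crossover pattern
            stacked = np.stack([
                cohort.hap_ancestry[i, 0] * 2 + cohort.hap_alleles[i, 0],
                cohort.hap_ancestry[i, 1] * 2 + cohort.hap_alleles[i, 1],
            ])
            packed = _gamete(stacked, model, rng)
            anc[s] = packed // 2
            alle[s] = packed % 2
        new_anc.append(anc)
        new_all.append(alle)
        ped.append((cid, p1, p2))
        child_ids.append(cid)
    new_anc = np.stack(new_anc)
    new_all = np.stack(new_all)
    geno_children = new_all.sum(axis=1).astype(float)
    if missing_rate > 0:
        mask = rng.random(geno_children.shape) < missing_rate
        geno_children[mask] = np.nan
    gen_df = pd.DataFrame(geno_children, index=pd.Index(child_ids, name="individual_id"),
                          columns=model.snp_ids)
    la_df = pd.DataFrame(new_anc.sum(axis=1), index=gen_df.index, columns=model.snp_ids)
    return SimulatedCohort(
        genotypes=pd.concat([cohort.genotypes, gen_df]),
        local_ancestry=pd.concat([cohort.local_ancestry, la_df]).astype(int),
        samples=cohort.samples,
        snps=cohort.snps,
        truth=cohort.truth,
        pedigree=cohort.pedigree + ped,
        hap_ancestry=np.concatenate([cohort.hap_ancestry, new_anc]),
        hap_alleles=np.concatenate([cohort.hap_alleles, new_all]),
        model=model,
        params=cohort.params,
    )


def simulate_covariates_ut(n_ind: int, seed: int = 0,
                           age_mean: float = 41.06, age_sd: float = 11.9,
                           age_range=(25.0, 65.0),
                           female_prob: float = 107.0 / 157.0,
                           edu_mean: float = 13.15, edu_sd: float = 2.4,
                           bmi_mean: float = 32.36, bmi_sd: float = 9.4,
                           ut_self_mean: float = 1.62,
                           ut_other_mean: float = 1.48,
                           individual_ids=None) -> pd.DataFrame:
    """Covariate and unfair-treatment table.

    Defaults match the target cohort's summary statistics: age ≈ 41 (SD 12,
    range 25–65 by the sampling design), ≈68% female, education ≈ 13.2 years,
    BMI ≈ 32.4, UT counts Poisson-like with means ≈1.6 (self) and ≈1.5
    (other), hard-truncated to the questionnaire's 0–9 range.
    """
    for v, name in ((age_sd, "age_sd"), (edu_sd, "edu_sd"), (bmi_sd, "bmi_sd")):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if not (0.0 <= female_prob <= 1.0):
        raise ValueError("female_prob must lie in [0,1]")
    if min(ut_self_mean, ut_other_mean) < 0:
        raise ValueError("UT means must be non-negative")
    rng = _rng(seed, 5)
    age = np.clip(rng.normal(age_mean, age_sd, n_ind), *age_range)
    sex = (rng.random(n_ind) < female_prob).astype(int)  # 0=male, 1=female
    edu = np.clip(np.round(rng.normal(edu_mean, edu_sd, n_ind)), 5, 20)
    bmi = np.clip(rng.normal(bmi_mean, bmi_sd, n_ind), 16.0, 65.0)
    ut_self = np.minimum(rng.poisson(ut_self_mean, n_ind), 9)
    ut_other = np.minimum(rng.poisson(ut_other_mean, n_ind), 9)
    ids = (pd.Index(individual_ids, name="individual_id") if individual_ids is not None
           else pd.Index([f"ind{i:04d}" for i in range(n_ind)], name="individual_id"))
    return pd.DataFrame(
        {"age": age, "sex": sex, "education": edu, "bmi": bmi,
         "ut_self": ut_self, "ut_other": ut_other},
        index=ids,
    )


def _linear_predictor(cohort: SimulatedCohort, model: PhenotypeModel) -> np.ndarray:
    cov = cohort.samples
    la = cohort.local_ancestry
    geno = cohort.genotypes
    n = len(cov)
    ga = la.mean(axis=1).to_numpy() / 2.0
    lp = (
        model.intercept
        + model.beta_age * cov["age"].to_numpy()
        + model.beta_sex * cov["sex"].to_numpy()
        + model.beta_edu * cov["education"].to_numpy()
        + model.beta_bmi * cov["bmi"].to_numpy()
        + model.beta_globalanc * ga
        + model.beta_ut_self * cov["ut_self"].to_numpy()
        + model.beta_ut_other * cov["ut_other"].to_numpy()
    )
    m = geno.shape[1]
    from .joint import code_ut

    def _g(idx):
        if not (0 <= int(idx) < m):
            raise ValueError(f"causal SNP index {idx} out of range")
        g = geno.iloc[:, int(idx)].to_numpy(dtype=float)
        return np.where(np.isfinite(g), g, 0.0)

    for idx, b in model.causal_snps.items():
        lp = lp + b * _g(idx)
    for idx, b in model.causal_ancestry.items():
        if not (0 <= int(idx) < m):
            raise ValueError(f"causal ancestry index {idx} out of range")
        lp = lp + b * la.iloc[:, int(idx)].to_numpy(dtype=float)
    for (idx, ut_var, coding), b in model.interactions.items():
        u = code_ut(cov[ut_var].to_numpy(), coding)
        lp = lp + b * _g(idx) * u
    assert lp.shape == (n,)
    return lp


def simulate_phenotype(cohort: SimulatedCohort, model: PhenotypeModel,
                       seed: int = 0, response: str = "sbp",
                       med_flag=None) -> pd.DataFrame:
    """Generate one BP response and its raw/medicated decomposition.

    The latent (adjusted-scale) phenotype is linear predictor + N(0, noise_sd)
    noise.  The medication flag is logistic in the *noise-free* latent value
    (higher latent BP → more likely medicated); raw readings subtract the
    medication offset from medicated individuals so the pipeline's
    add-the-offset adjustment round-trips exactly.  Returns a copy of the
    sample table with ``{response}_raw``, ``{response}_latent`` and
    ``med_flag`` columns.
    """
    rng = _rng(seed, 6, {"sbp": 0, "dbp": 1}[response])
    lp = _linear_predictor(cohort, model)
    noise = rng.normal(0.0, model.noise_sd, lp.size) if model.noise_sd > 0 else np.zeros(lp.size)
    latent = lp + noise
    out = cohort.samples.copy()
    if med_flag is None:
        from scipy.special import expit
        p_med = expit((lp - model.med_center) / model.med_scale)
        med_flag = rng.random(lp.size) < p_med
    med_flag = np.asarray(med_flag, dtype=bool)
    out[f"{response}_latent"] = latent
    out[f"{response}_raw"] = latent - model.med_offset * med_flag
    out["med_flag"] = med_flag
    return out


class CohortSimulator:
    """End-to-end generator for a synthetic admixed cohort.

    Defaults are the stated world of the target study: 157 individuals of whom
    37 are relatives of the 120 founders, ~27.6k SNPs (scale down via
    ``n_snps``), two-way admixture with alpha = 0.8 over 7 generations,
    Fst = 0.15 ancestral differentiation, 1% missing genotypes, Table-1-scale
    covariates and ≈30% medicated.

    Causal effects are planted through the two :class:`PhenotypeModel`s.
    """

    def __init__(self, n_ind: int = 157, n_snps: int = 27559,
                 n_related: int = 37, fst: float = 0.15,
                 alpha: float = 0.8, generations: int = 7,
                 missing_rate: float = 0.01, seed: int = 0,
                 sbp_model: PhenotypeModel | None = None,
                 dbp_model: PhenotypeModel | None = None,
                 chrom_lengths=DEFAULT_CHROM_LENGTHS):
        if n_related >= n_ind:
            raise ValueError("n_related must be smaller than n_ind")
        self.n_ind = n_ind
        self.n_snps = n_snps
        self.n_related = n_related
        self.fst = fst
        self.alpha = alpha
        self.generations = generations
        self.missing_rate = missing_rate
        self.seed = seed
        self.sbp_model = sbp_model or PhenotypeModel()
        self.dbp_model = dbp_model or dbp_default_model()
        self.chrom_lengths = chrom_lengths

    def simulate(self, seed: int | None = None) -> SimulatedCohort:
        seed = self.seed if seed is None else seed
        n_founders = self.n_ind - self.n_related
        model = simulate_ancestral_frequencies(
            self.n_snps, fst=self.fst, seed=seed, chrom_lengths=self.chrom_lengths
        )
        params = AdmixtureParams(alpha=self.alpha, generations=self.generations, seed=seed)
        local, haps = simulate_local_ancestry(model, params, n_founders)
        genotypes, alleles = simulate_genotypes(
            model, haps, seed=seed, missing_rate=self.missing_rate
        )
        cohort = SimulatedCohort(
            genotypes=genotypes, local_ancestry=local.astype(int),
            samples=pd.DataFrame(index=genotypes.index), snps=model.snp_table(),
            truth={}, pedigree=[], hap_ancestry=haps, hap_alleles=alleles,
            model=model, params=params,
        )
        cohort = simulate_relatives(cohort, n_parent_offspring=self.n_related,
                                    seed=seed, missing_rate=self.missing_rate)
        ids = cohort.genotypes.index
        cohort.samples = simulate_covariates_ut(len(ids), seed=seed, individual_ids=ids)
        sbp = simulate_phenotype(cohort, self.sbp_model, seed=seed, response="sbp")
        cohort.samples = simulate_phenotype(
            cohort, self.dbp_model, seed=seed, response="dbp",
            med_flag=sbp["med_flag"],
        )
        cohort.samples[["sbp_latent", "sbp_raw"]] = sbp[["sbp_latent", "sbp_raw"]]
        cohort.truth = {
            "seed": int(seed),
            "alpha": self.alpha,
            "generations": self.generations,
            "fst": self.fst,
            "causal_snps_sbp": {str(k): v for k, v in self.sbp_model.causal_snps.items()},
            "causal_ancestry_sbp": {str(k): v for k, v in self.sbp_model.causal_ancestry.items()},
            "interactions_sbp": {str(k): v for k, v in self.sbp_model.interactions.items()},
            "causal_snps_dbp": {str(k): v for k, v in self.dbp_model.causal_snps.items()},
            "pedigree": [list(t) for t in cohort.pedigree],
        }
        return cohort


def write_cohort(cohort: SimulatedCohort, outdir, genotype_format: str = "tsv") -> dict:
    """Write a cohort to disk (genotypes, ancestry TSV, samples CSV, truth JSON)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    if genotype_format == "vcf":
        paths["genotypes"] = os.path.join(outdir, "genotypes.vcf")
        write_genotypes_vcf(paths["genotypes"], cohort.genotypes, cohort.snps)
    else:
        paths["genotypes"] = os.path.join(outdir, "genotypes.tsv")
        write_genotypes_tsv(paths["genotypes"], cohort.genotypes)
    paths["local_ancestry"] = os.path.join(outdir, "local_ancestry.tsv")
    cohort.local_ancestry.to_csv(paths["local_ancestry"], sep="\t", index_label="individual_id")
    paths["samples"] = os.path.join(outdir, "samples.csv")
    write_samples(paths["samples"], cohort.samples)
    paths["snps"] = os.path.join(outdir, "snps.tsv")
    cohort.snps.to_csv(paths["snps"], sep="\t", index_label="snp_id")
    paths["truth"] = os.path.join(outdir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    return paths
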