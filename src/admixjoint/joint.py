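"""Bayesian joint admixture-and-association mapping.

The joint statistic chains two stages of evidence per SNP:

* **Stage A (admixture prior).**  The admixture-mapping effect estimate for
  local ancestry at the SNP is converted to an approximate Bayes factor and
  combined with a flat prior of one expected signal per effective admixture
  test (``1/t_adm``), yielding the admixture posterior ``P_adm``.  Because the
  effective admixture test count is small (ancestry blocks are long), genuinely
  ancestry-associated regions receive a much larger prior than a genome-wide
  Bonferroni would grant — this is how the scan prioritises regions of target
  (African) ancestry.

* **Stage B (association evidence).**  Within each local-ancestry stratum
  (0/1/2 copies), adjusted BP is regressed on the focal term (genotype for
  Models 1–2, the SNP×UT interaction for Model 3); stratum estimates are pooled
  by inverse-variance-weighted fixed effects.  The pooled estimate's Bayes
  factor is combined with the association prior
  ``pi_assoc = P_adm / (t_assoc / t_adm)`` — a *partial Bonferroni*: the
  admixture posterior is discounted only by the residual per-block SNP burden,
  not by the full SNP count.

A SNP is declared significant when the resulting joint posterior probability
is ≥ 0.5.

The three progressive models:

* Model 1 — BP ~ SNP + covariates (focal: SNP);
* Model 2 — adds an unfair-treatment (UT) count or dichotomised UT covariate
  (focal: SNP);
* Model 3 — adds the SNP×UT interaction (focal: the interaction), restricted
  to SNPs with MAF > 10% so minor-allele homozygotes exist at both UT levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import compute_maf
from .scan import SCAN_COVARIATES, _scan_ols, fit_ols

__all__ = [
    "dichotomize_ut",
    "StratumFit",
    "stratified_association",
    "ivw_combine",
    "approx_bayes_factor",
    "posterior_from_prior",
    "BayesConfig",
    "JointAdmixtureAssociation",
    "model3_maf_filter",
]

PI_EPS = 1e-12


def dichotomize_ut(ut_count, scheme: str):
    """Dichotomise an unfair-treatment count (0–9).

    ``no_yes``: 0 → 0 (No), ≥1 → 1 (Yes).  ``low_high``: ≤2 → 0 (Low), ≥3 → 1
    (High) — the threshold at which a weathering-type effect of cumulative
    unfair treatment is expected to manifest.
    """
    x = np.asarray(ut_count)
    if np.any((x < 0) | (x > 9)):
        raise ValueError("UT counts must lie in [0, 9]")
    if scheme == "no_yes":
        out = (x >= 1).astype(int)
    elif scheme == "low_high":
        out = (x >= 3).astype(int)
    else:
        raise ValueError(f"unknown dichotomisation scheme {scheme!r}")
    return out if out.ndim else int(out)


def code_ut(ut_count, coding: str):
    """UT covariate under a coding: raw ``count`` or a dichotomisation."""
    if coding == "count":
        return np.asarray(ut_count, dtype=float)
    return dichotomize_ut(ut_count, coding).astype(float)


@dataclass
class StratumFit:
    """Focal-term fit within one local-ancestry stratum."""

    stratum: int
    n: int
    beta: float
    se: float


@dataclass
class BayesConfig:
    """Tunables of the Bayesian stage.

    prior_effect_sd : prior SD of the standardised effect, as a fraction of
        the phenotype SD (the prior variance is ``W = (prior_effect_sd *
        SD(y))**2``).  0.2 encodes "a plausible signal shifts BP by a fifth of
        a phenotypic SD".
    pi_mode : "one_over_t_adm" (prior 1/t_adm) or "alpha_over_t_adm"
        (0.05/t_adm).
    min_stratum_n : smallest stratum sample size allowed to contribute.
    """

    prior_effect_sd: float = 0.2
    pi_mode: str = "one_over_t_adm"
    min_stratum_n: int = 10

    def __post_init__(self):
        if self.prior_effect_sd <= 0:
            raise ValueError("prior_effect_sd must be positive")
        if self.pi_mode not in ("one_over_t_adm", "alpha_over_t_adm"):
            raise ValueError(f"unknown pi_mode {self.pi_mode!r}")

    def stage_a_prior(self, t_adm: float) -> float:
        pi = (0.05 if self.pi_mode == "alpha_over_t_adm" else 1.0) / t_adm
        return float(np.clip(pi, PI_EPS, 1.0 - PI_EPS))


def approx_bayes_factor(beta: float, se: float, prior_variance: float) -> float:
    """Approximate Bayes factor for a normal effect estimate vs a point null.

    With ``z = beta/se`` and prior effect variance ``W``:

        ABF = sqrt(se^2 / (se^2 + W)) * exp(z^2 W / (2 (se^2 + W)))

    Values above 1 favour association.  ``W = 0`` returns exactly 1 (a
    point-mass prior at zero carries no evidence either way).
    """
    if not (np.isfinite(beta) and np.isfinite(se) and np.isfinite(prior_variance)):
        raise ValueError("non-finite input to approx_bayes_factor")
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_variance < 0:
        raise ValueError("prior variance must be non-negative")
    z2 = (beta / se) ** 2
    v = se * se
    shrink = v / (v + prior_variance)
    log_abf = 0.5 * math.log(shrink) + z2 * prior_variance / (2.0 * (v + prior_variance))
    if log_abf > 700.0:  # exp would overflow; posterior saturates at 1 anyway
        return math.inf
    return float(math.exp(log_abf))


def posterior_from_prior(prior: float, abf: float) -> float:
    """Posterior probability from prior odds scaled by a Bayes factor."""
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must lie strictly in (0,1), got {prior}")
    if abf < 0:
        raise ValueError("Bayes factor must be non-negative")
    odds = abf * prior / (1.0 - prior)
    if math.isinf(odds):
        return 1.0
    return odds / (1.0 + odds)


def ivw_combine(fits: list[StratumFit]):
    """Inverse-variance-weighted fixed-effects pooling of stratum fits.

    Returns ``(beta, se, z, p)`` with a two-sided normal p-value.
    """
    if not fits:
        raise ValueError("no strata to combine")
    betas = np.array([f.beta for f in fits])
    ses = np.array([f.se for f in fits])
    if np.any(ses <= 0):
        raise ValueError("stratum standard errors must be positive")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, z, p


def _model_design(g, covariates, ut, model, focal_first=True):
    """Design columns and names for one stratum fit; focal column is first."""
    cols = [g]
    names = ["genotype"]
    if model >= 2:
        cols.append(ut)
        names.append("ut")
    if model == 3:
        cols.append(g * ut)
        names.append("genotype_x_ut")
    X = np.column_stack([np.ones(g.size)] + cols + [covariates])
    names = ["intercept"] + names + [f"c{i}" for i in range(covariates.shape[1])]
    return X, names


def stratified_association(
    y, genotype, local_ancestry, covariates, model: int = 1,
    ut=None, min_stratum_n: int = 10, wald_dist: str = "t",
):
    """Per-stratum focal fits for one SNP.

    Splits individuals by local-ancestry copies (0/1/2), fits the model within
    each stratum and returns the contributing :class:`StratumFit` list plus an
    exclusion reason ("" when at least one stratum contributes).  A stratum is
    dropped when it is smaller than ``min_stratum_n``, its focal term has no
    variance, or its design is collinear / lacks residual degrees of freedom —
    mirroring the exclusion of SNPs whose genotypes have no variance once
    stratified by ancestry.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotype, dtype=float)
    la = np.asarray(local_ancestry, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if model >= 2:
        if ut is None:
            raise ValueError("models 2 and 3 require a UT covariate")
        ut = np.asarray(ut, dtype=float)
    focal = "genotype" if model in (1, 2) else "genotype_x_ut"
    fits: list[StratumFit] = []
    for stratum in (0, 1, 2):
        mask = (la == stratum) & np.isfinite(g) & np.isfinite(y)
        n_s = int(mask.sum())
        if n_s < min_stratum_n:
            continue
        gs = g[mask]
        uts = ut[mask] if model >= 2 else None
        focal_vec = gs if model in (1, 2) else gs * uts
        if np.var(focal_vec) <= 1e-12:
            continue
        X, names = _model_design(gs, C[mask], uts, model)
        if n_s <= X.shape[1]:
            continue
        try:
            res = fit_ols(y[mask], X, names=names, wald_dist=wald_dist)
        except ValueError:
            continue  # collinear design inside the stratum
        r = next(rr for rr in res if rr.term == focal)
        if not (np.isfinite(r.se) and r.se > 0):
            continue
        fits.append(StratumFit(stratum=stratum, n=n_s, beta=r.beta, se=r.se))
    reason = "" if fits else "no stratum variance"
    return fits, reason


def model3_maf_filter(genotypes: pd.DataFrame, threshold: float = 0.10) -> pd.Index:
    """SNPs eligible for the interaction model: MAF strictly above ``threshold``."""
    mafs = np.array([compute_maf(genotypes[c]) for c in genotypes.columns])
    return genotypes.columns[mafs > threshold]


class JointAdmixtureAssociation(BaseEstimator):
    """Joint Bayesian admixture-and-association scan (Models 1–3).

    Parameters
    ----------
    model : {1, 2, 3}
    ut_variable : {None, "ut_self", "ut_other"}
        Required for models 2 and 3.
    ut_coding : {"count", "no_yes", "low_high"}
    prior_effect_sd, pi_mode, min_stratum_n : see :class:`BayesConfig`.
    maf_min_model3 : float, default 0.10
        Strict MAF filter applied before the interaction model.
    covariates : covariate column names taken from the sample table.

    Attributes
    ----------
    results_ : pandas.DataFrame, one row per scanned SNP with the admixture
        ABF/posterior, association prior, IVW-combined effect, joint posterior
        and the ≥0.5 significance flag.
    effective_tests_ : the (t_adm, t_assoc) pair used.
    prior_variance_ : the prior effect variance W actually used.
    """

    def __init__(self, model: int = 1, ut_variable: str | None = None,
                 ut_coding: str = "count", prior_effect_sd: float = 0.2,
                 pi_mode: str = "one_over_t_adm", min_stratum_n: int = 10,
                 maf_min_model3: float = 0.10,
                 covariates: tuple = SCAN_COVARIATES, wald_dist: str = "t"):
        self.model = model
        self.ut_variable = ut_variable
        self.ut_coding = ut_coding
        self.prior_effect_sd = prior_effect_sd
        self.pi_mode = pi_mode
        self.min_stratum_n = min_stratum_n
        self.maf_min_model3 = maf_min_model3
        self.covariates = covariates
        self.wald_dist = wald_dist

    def _config(self) -> BayesConfig:
        return BayesConfig(prior_effect_sd=self.prior_effect_sd,
                           pi_mode=self.pi_mode, min_stratum_n=self.min_stratum_n)

    def fit(self, genotypes: pd.DataFrame, y, *, local_ancestry: pd.DataFrame,
            samples: pd.DataFrame, effective_tests, snps: pd.DataFrame = None):
        """Run the joint scan over the columns of ``genotypes``.

        ``local_ancestry`` must share the index and columns of ``genotypes``;
        ``effective_tests`` is an :class:`admixjoint.ancestry.EffectiveTests`.
        """
        if self.model not in (1, 2, 3):
            raise ValueError(f"model must be 1, 2 or 3, got {self.model}")
        if self.model >= 2 and self.ut_variable not in ("ut_self", "ut_other"):
            raise ValueError("models 2 and 3 require ut_variable")
        cfg = self._config()
        y = pd.Series(y).loc[genotypes.index]
        cov = samples.loc[genotypes.index, list(self.covariates)]
        keep = y.notna() & cov.notna().all(axis=1)
        if self.model >= 2:
            keep &= samples.loc[genotypes.index, self.ut_variable].notna()
        idx = genotypes.index[keep]
        yv = y.loc[idx].to_numpy(dtype=float)
        C = cov.loc[idx].to_numpy(dtype=float)
        ut = (code_ut(samples.loc[idx, self.ut_variable].to_numpy(), self.ut_coding)
              if self.model >= 2 else None)

        snp_ids = genotypes.columns
        if self.model == 3:
            snp_ids = model3_maf_filter(genotypes[snp_ids], self.maf_min_model3)
        G = genotypes.loc[idx, snp_ids]
        LA = local_ancestry.loc[idx, snp_ids]

        t_adm = float(effective_tests.t_adm)
        t_assoc = float(effective_tests.t_assoc)
        W = (self.prior_effect_sd * float(np.std(yv, ddof=1))) ** 2
        pi0 = cfg.stage_a_prior(t_adm)
        burden_ratio = max(t_assoc / t_adm, 1.0)

        # Stage A: admixture regression per SNP (vectorised; same covariates)
        Cfull = np.column_stack([np.ones(len(idx)), C])
        adm_beta, adm_se, _, _, _, adm_reason = _scan_ols(
            yv, LA.to_numpy(dtype=float), Cfull, wald_dist=self.wald_dist
        )

        rows = []
        Gmat = G.to_numpy(dtype=float)
        LAmat = LA.to_numpy(dtype=float)
        for j, sid in enumerate(snp_ids):
            row = self._one_snp(
                yv, Gmat[:, j], LAmat[:, j], C, ut,
                adm_beta[j], adm_se[j], adm_reason[j],
                pi0, burden_ratio, W, cfg,
            )
            row["snp_id"] = sid
            rows.append(row)
        res_cols = ["snp_id", "adm_beta", "adm_se", "adm_abf", "adm_posterior",
                    "assoc_prior", "combined_beta", "combined_se", "combined_z",
                    "combined_p", "assoc_abf", "joint_posterior", "n_strata",
                    "significant", "excluded_reason"]
        res = pd.DataFrame(rows, columns=res_cols).set_index("snp_id")
        res.insert(0, "model", self.model)
        res.insert(1, "ut_variable", self.ut_variable or "none")
        res.insert(2, "ut_coding", self.ut_coding if self.model >= 2 else "none")
        if snps is not None:
            ann = snps.reindex(res.index)
            for col in ("closest_gene", "pos", "chrom"):
                if col in ann:
                    res.insert(3, col, ann[col])
        self.results_ = res
        self.effective_tests_ = effective_tests
        self.prior_variance_ = W
        self.n_individuals_ = len(idx)
        return self

    def _one_snp(self, y, g, la, C, ut, adm_beta, adm_se, adm_reason,
                 pi0, burden_ratio, W, cfg):
        out = dict.fromkeys(
            ("adm_beta", "adm_se", "adm_abf", "adm_posterior", "assoc_prior",
             "combined_beta", "combined_se", "combined_z", "combined_p",
             "assoc_abf", "joint_posterior"), np.nan)
        out["n_strata"] = 0
        out["significant"] = False
        out["excluded_reason"] = ""
        # Stage A
        if np.isfinite(adm_beta) and np.isfinite(adm_se) and adm_se > 0:
            abf_adm = approx_bayes_factor(adm_beta, adm_se, W)
            p_adm = posterior_from_prior(pi0, abf_adm)
            out.update(adm_beta=adm_beta, adm_se=adm_se, adm_abf=abf_adm,
                       adm_posterior=p_adm)
        else:
            # no usable local-ancestry evidence (e.g. constant ancestry):
            # fall back to the uninformed stage-A prior
            p_adm = pi0
            out["adm_posterior"] = p_adm
        pi_assoc = float(np.clip(p_adm / burden_ratio, PI_EPS, 1.0 - PI_EPS))
        out["assoc_prior"] = pi_assoc
        # Stage B
        fits, reason = stratified_association(
            y, g, la, C, model=self.model, ut=ut,
            min_stratum_n=cfg.min_stratum_n, wald_dist=self.wald_dist,
        )
        if reason:
            out["excluded_reason"] = reason
            return out
        beta, se, z, p = ivw_combine(fits)
        abf = approx_bayes_factor(beta, se, W)
        post = posterior_from_prior(pi_assoc, abf)
        out.update(n_strata=len(fits), combined_beta=beta, combined_se=se,
                   combined_z=z, combined_p=p, assoc_abf=abf,
                   joint_posterior=post, significant=post >= 0.5)
        return out

    @property
    def hits_(self) -> pd.DataFrame:
        """Rows with joint posterior ≥ 0.5."""
        return self.results_[self.results_["significant"]]

    def manhattan_table(self) -> pd.DataFrame:
        res = self.results_
        cols = [c for c in ("chrom", "pos") if c in res]
        return res[cols + ["joint_posterior"]].copy()
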