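"""Permutation-based false-positive confirmation of joint hits.

Every SNP whose joint posterior reaches 0.5 is re-tested under the
permutation null: phenotype and phenotype-linked covariates are shuffled as a
block against the fixed genotype/ancestry data, the full joint statistic
(admixture prior included, by default) is recomputed on each permuted dataset,
and the number of permutations reaching a joint posterior ≥ 0.5 is counted.
A hit is *confirmed* when that count is at most ``floor(alpha * n_perm)`` —
with the canonical 10,000 permutations at alpha = 0.05, exactly 500.

Genotype-derived quantities (global ancestry, PC scores) stay in the fixed
block by default: they are functions of the genotypes, and shuffling them
against the genotypes would break the structure of the null.  Setting
``literal_covariate_shuffle=True`` moves them into the shuffled block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .joint import JointAdmixtureAssociation

__all__ = ["PermutationPlan", "permute_labels", "PermutationConfirmation",
           "confirm_hits", "threshold_count"]

#: phenotype-linked columns shuffled together by default
DEFAULT_PHENO_BLOCK = (
    "sbp_adj", "dbp_adj", "sbp_raw", "dbp_raw", "med_flag",
    "age", "sex", "education", "bmi", "ut_self", "ut_other",
)
#: genotype-derived columns kept fixed by default
DEFAULT_GENO_BLOCK = (
    "global_ancestry", "pc1", "pc2", "pc3", "pc4", "pc5",
    "pc6", "pc7", "pc8", "pc9", "pc10",
)


def threshold_count(alpha: float, n_perm: int) -> int:
    """Largest exceedance count still consistent with the alpha level."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return math.floor(alpha * n_perm)


@dataclass
class PermutationPlan:
    """Shuffling plan: which columns travel with the phenotype."""

    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 385
    shuffle_block_pheno: tuple = DEFAULT_PHENO_BLOCK
    shuffle_block_geno: tuple = DEFAULT_GENO_BLOCK

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        overlap = set(self.shuffle_block_pheno) & set(self.shuffle_block_geno)
        if overlap:
            raise ValueError(f"blocks overlap: {sorted(overlap)}")

    @property
    def threshold_count(self) -> int:
        return threshold_count(self.alpha, self.n_perm)


def _perm_rng(seed: int, perm_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), int(perm_index)]))


def permute_labels(samples: pd.DataFrame, plan: PermutationPlan,
                   perm_index: int) -> pd.DataFrame:
    """One permuted sample table.

    A single random permutation of individual indices is applied jointly to
    every phenotype-block column present; all other columns stay put.
    ``perm_index = 0`` is reserved for the identity permutation, so that
    permutation 0 reproduces the observed data exactly.
    """
    out = samples.copy()
    if perm_index == 0:
        return out
    rng = _perm_rng(plan.seed, perm_index)
    perm = rng.permutation(len(samples))
    cols = [c for c in plan.shuffle_block_pheno if c in samples.columns]
    out[cols] = samples[cols].to_numpy()[perm]
    return out


class PermutationConfirmation(BaseEstimator):
    """Confirm joint hits against the permutation null.

    Parameters
    ----------
    n_perm : int, default 10_000
    alpha : float, default 0.05
    seed : int, default 385
    recompute_prior : bool, default True
        Recompute the admixture prior inside each permutation (the full joint
        statistic); with ``False`` the observed association prior is reused.
    literal_covariate_shuffle : bool, default False
        Also shuffle genotype-derived covariates (global ancestry, PCs).

    Attributes
    ----------
    results_ : DataFrame with snp_id, model, n_perm, exceed_count,
        threshold_count, confirmed.
    observed_ : per-hit observed joint posterior recomputed through the same
        single-SNP code path the permutations use.
    """

    def __init__(self, n_perm: int = 10_000, alpha: float = 0.05, seed: int = 385,
                 recompute_prior: bool = True, literal_covariate_shuffle: bool = False,
                 max_evaluations: int = 20_000_000):
        self.n_perm = n_perm
        self.alpha = alpha
        self.seed = seed
        self.recompute_prior = recompute_prior
        self.literal_covariate_shuffle = literal_covariate_shuffle
        self.max_evaluations = max_evaluations

    def _plan(self) -> PermutationPlan:
        pheno = DEFAULT_PHENO_BLOCK
        geno = DEFAULT_GENO_BLOCK
        if self.literal_covariate_shuffle:
            pheno = pheno + geno
            geno = ()
        return PermutationPlan(n_perm=self.n_perm, alpha=self.alpha,
                               seed=self.seed, shuffle_block_pheno=pheno,
                               shuffle_block_geno=geno)

    def fit(self, hits, *, estimator: JointAdmixtureAssociation,
            genotypes: pd.DataFrame, local_ancestry: pd.DataFrame,
            samples: pd.DataFrame, response: str, effective_tests,
            snps: pd.DataFrame = None):
        """Run the permutation confirmation for each hit.

        ``hits`` is an iterable of SNP IDs (or the estimator's ``hits_``
        frame); ``estimator`` supplies the fitted model configuration, and the
        remaining arguments are the observed dataset.
        """
        if isinstance(hits, (pd.DataFrame, pd.Series)):
            hit_ids = list(hits.index)
        else:
            hit_ids = list(hits)
        if not hit_ids:
            self.results_ = pd.DataFrame(
                columns=["snp_id", "model", "n_perm", "exceed_count",
                         "threshold_count", "confirmed"]
            ).set_index("snp_id")
            self.observed_ = pd.Series(dtype=float)
            return self
        if self.n_perm * len(hit_ids) > self.max_evaluations:
            raise ValueError(
                f"{self.n_perm} permutations x {len(hit_ids)} hits exceeds the "
                f"compute budget ({self.max_evaluations}); reduce n_perm or hits"
            )
        plan = self._plan()
        thr = plan.threshold_count
        single = JointAdmixtureAssociation(**estimator.get_params())

        def posterior(samp: pd.DataFrame, sid) -> float:
            single.fit(
                genotypes[[sid]], samp[response], local_ancestry=local_ancestry[[sid]],
                samples=samp, effective_tests=effective_tests,
            )
            return float(single.results_["joint_posterior"].iloc[0])

        observed = {sid: posterior(samples, sid) for sid in hit_ids}
        if not self.recompute_prior:
            fixed_priors = {
                sid: float(estimator.results_.loc[sid, "assoc_prior"]) for sid in hit_ids
            }
        rows = []
        exceed = dict.fromkeys(hit_ids, 0)
        for b in range(1, self.n_perm + 1):
            perm_samples = permute_labels(samples, plan, b)
            for sid in hit_ids:
                if self.recompute_prior:
                    post = posterior(perm_samples, sid)
                else:
                    post = self._posterior_fixed_prior(
                        single, perm_samples, sid, genotypes, local_ancestry,
                        response, effective_tests, fixed_priors[sid],
                    )
                if post >= 0.5:
                    exceed[sid] += 1
        for sid in hit_ids:
            rows.append({
                "snp_id": sid,
                "model": estimator.model,
                "n_perm": self.n_perm,
                "exceed_count": exceed[sid],
                "threshold_count": thr,
                "confirmed": exceed[sid] <= thr,
            })
        self.results_ = pd.DataFrame(rows).set_index("snp_id")
        self.observed_ = pd.Series(observed, name="joint_posterior")
        self.plan_ = plan
        return self

    @staticmethod
    def _posterior_fixed_prior(single, samp, sid, genotypes, local_ancestry,
                               response, effective_tests, prior):
        from .joint import approx_bayes_factor, posterior_from_prior

        single.fit(
            genotypes[[sid]], samp[response], local_ancestry=local_ancestry[[sid]],
            samples=samp, effective_tests=effective_tests,
        )
        row = single.results_.iloc[0]
        if not np.isfinite(row["combined_beta"]):
            return np.nan
        abf = approx_bayes_factor(row["combined_beta"], row["combined_se"],
                                  single.prior_variance_)
        return posterior_from_prior(prior, abf)


def confirm_hits(hits, estimator, genotypes, local_ancestry, samples, response,
                 effective_tests, n_perm=10_000, alpha=0.05, seed=385,
                 recompute_prior=True, snps=None) -> pd.DataFrame:
    """Functional wrapper around :class:`PermutationConfirmation`."""
    pc = PermutationConfirmation(n_perm=n_perm, alpha=alpha, seed=seed,
                                 recompute_prior=recompute_prior)
    pc.fit(hits, estimator=estimator, genotypes=genotypes,
           local_ancestry=local_ancestry, samples=samples, response=response,
           effective_tests=effective_tests, snps=snps)
    return pc.results_
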