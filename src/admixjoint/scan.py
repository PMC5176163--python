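"""Frequentist genome scans: admixture mapping and association mapping.

Both scans are ordinary least squares of medication-adjusted blood pressure on
a focal per-SNP column — the 0/1/2 local-ancestry code for admixture mapping,
the 0/1/2 genotype for association mapping — with a fixed covariate block
(global ancestry, sex, age, education, BMI, PC1–PC10).  Multiple testing is
handled by Bonferroni correction against the analysis-specific burden: the
mean number of ancestry switches for admixture mapping, the number of SNPs for
association mapping.

The per-SNP fits are computed by residualising the response and the focal
columns against the covariate block (Frisch–Waugh–Lovell), which is
algebraically identical to the full OLS fit but vectorises across tens of
thousands of SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "RegressionResult",
    "fit_ols",
    "bonferroni_threshold",
    "AdmixtureScan",
    "AssociationScan",
    "admixture_scan",
    "association_scan",
    "screen_covariates",
    "SCAN_COVARIATES",
]

#: covariate columns used by every scan, in model order
SCAN_COVARIATES = (
    "global_ancestry", "sex", "age", "education", "bmi",
    "pc1", "pc2", "pc3", "pc4", "pc5", "pc6", "pc7", "pc8", "pc9", "pc10",
)


@dataclass
class RegressionResult:
    term: str
    beta: float
    se: float
    stat: float
    p: float
    n: int
    df_resid: int


def fit_ols(y, X, names=None, wald_dist: str = "t") -> list[RegressionResult]:
    """Least-squares fit with per-term Wald tests.

    Parameters
    ----------
    y : (n,) response
    X : (n, k) design matrix, caller includes the intercept column
    names : term labels (defaults to x0..x{k-1})
    wald_dist : {"t", "normal"}
        Reference distribution for the two-sided Wald p-value; ``t`` with
        n - k degrees of freedom is the default, appropriate at the small
        sample sizes admixed-cohort studies typically have.

    Raises
    ------
    ValueError on rank deficiency (reporting the offending columns) or n <= k.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if n <= k:
        raise ValueError(f"n={n} observations for k={k} parameters")
    Q, R, piv, rank = _qr_with_rank(X)
    if rank < k:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")
    beta = np.linalg.solve(R, Q.T @ y)[np.argsort(piv)]
    resid = y - X @ beta
    df = n - k
    sigma2 = resid @ resid / df
    Rinv = np.linalg.inv(R)
    cov_piv = Rinv @ Rinv.T * sigma2
    inv_order = np.argsort(piv)
    cov = cov_piv[np.ix_(inv_order, inv_order)]
    se = np.sqrt(np.diag(cov))
    stat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    if wald_dist == "t":
        p = 2.0 * stats.t.sf(np.abs(stat), df)
    elif wald_dist == "normal":
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        raise ValueError(f"unknown wald_dist {wald_dist!r}")
    return [
        RegressionResult(names[j], float(beta[j]), float(se[j]), float(stat[j]),
                         float(p[j]), n, df)
        for j in range(k)
    ]


def _qr_with_rank(X, tol_factor: float = 1e-10):
    """Column-pivoted QR, truncated at numerical rank."""
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * tol_factor if diag.size else 0.0
    rank = int((diag > tol).sum())
    return Q, R, piv, rank


def bonferroni_threshold(alpha: float = 0.05, n_tests: float = 1.0) -> float:
    """Bonferroni significance threshold on the -log10(p) scale."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return float(-np.log10(alpha / n_tests))


# ---------------------------------------------------------------------------
# Vectorised per-SNP scan
# ---------------------------------------------------------------------------

def _scan_ols(y: np.ndarray, F: np.ndarray, C: np.ndarray, wald_dist: str = "t"):
    """Per-column OLS of y on [C | F[:, j]] via FWL residualisation.

    Missing focal values (NaN) trigger a per-SNP complete-case fit.  Returns
    arrays (beta, se, stat, p, n, excluded_reason) over columns of F.
    """
    n, m = F.shape
    kc = C.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    nn = np.full(m, 0, dtype=int)
    reason = np.array([""] * m, dtype=object)

    Q, _ = np.linalg.qr(C)
    ry_full = y - Q @ (Q.T @ y)

    finite = np.isfinite(F)
    complete = finite.all(axis=0)

    def _one(yv, fv, Cv, j):
        var = fv.var()
        if var <= 1e-12:
            reason[j] = "constant"
            return
        Qv, _ = np.linalg.qr(Cv)
        ry = yv - Qv @ (Qv.T @ yv)
        rf = fv - Qv @ (Qv.T @ fv)
        ss = rf @ rf
        nv = yv.size
        if ss <= 1e-10 * nv * var:
            reason[j] = "collinear"
            return
        df = nv - Cv.shape[1] - 1
        if df < 1:
            reason[j] = "insufficient_df"
            return
        b = (rf @ ry) / ss
        sse = ry @ ry - b * b * ss
        s2 = max(sse, 0.0) / df
        beta[j] = b
        se[j] = np.sqrt(s2 / ss)
        nn[j] = nv

    # fast path: all complete columns at once
    idx = np.flatnonzero(complete)
    if idx.size:
        Fc = F[:, idx]
        var = Fc.var(axis=0)
        RF = Fc - Q @ (Q.T @ Fc)
        ss = (RF * RF).sum(axis=0)
        ok = (var > 1e-12) & (ss > 1e-10 * n * np.maximum(var, 1e-300))
        df = n - kc - 1
        b = np.where(ss > 0, RF.T @ ry_full / np.where(ss > 0, ss, 1.0), np.nan)
        sse = ry_full @ ry_full - b * b * ss
        s2 = np.maximum(sse, 0.0) / df
        beta[idx[ok]] = b[ok]
        se[idx[ok]] = np.sqrt(s2[ok] / ss[ok])
        nn[idx[ok]] = n
        reason[idx[var <= 1e-12]] = "constant"
        reason[idx[(var > 1e-12) & ~ok]] = "collinear"

    for j in np.flatnonzero(~complete):
        mask = finite[:, j]
        nv = int(mask.sum())
        if nv <= kc + 1:
            reason[j] = "insufficient_df"
            continue
        _one(y[mask], F[mask, j], C[mask], j)

    with np.errstate(invalid="ignore", divide="ignore"):
        stat = beta / se
    dfs = nn - kc - 1
    if wald_dist == "t":
        p = np.where(np.isfinite(stat), 2.0 * stats.t.sf(np.abs(stat), np.maximum(dfs, 1)), np.nan)
    else:
        p = np.where(np.isfinite(stat), 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    return beta, se, stat, p, nn, reason


class _BaseScan(BaseEstimator):
    """Shared machinery for the per-SNP scans."""

    focal_label = "focal"

    def __init__(self, alpha: float = 0.05, n_tests: float | None = None,
                 covariates: tuple = SCAN_COVARIATES, wald_dist: str = "t"):
        self.alpha = alpha
        self.n_tests = n_tests
        self.covariates = covariates
        self.wald_dist = wald_dist

    def fit(self, X: pd.DataFrame, y: pd.Series, samples: pd.DataFrame = None,
            snps: pd.DataFrame = None):
        """Scan every column of X as the focal term.

        Parameters
        ----------
        X : DataFrame (individuals × SNPs) of focal values (genotype codes or
            local-ancestry codes); NaN allowed (per-SNP complete case).
        y : adjusted blood pressure, aligned to X's index.
        samples : DataFrame providing the covariate columns.
        snps : optional SNP table for chrom/pos annotation of results.
        """
        if samples is None:
            raise ValueError("samples table with covariate columns is required")
        y = pd.Series(y).loc[X.index]
        missing = [c for c in self.covariates if c not in samples.columns]
        if missing:
            raise ValueError(f"sample table lacks covariates: {missing}")
        cov = samples.loc[X.index, list(self.covariates)]
        keep = y.notna() & cov.notna().all(axis=1)
        yv = y[keep].to_numpy(dtype=float)
        C = np.column_stack([np.ones(keep.sum()), cov[keep].to_numpy(dtype=float)])
        F = X.loc[keep].to_numpy(dtype=float)
        beta, se, stat, p, nn, reason = _scan_ols(yv, F, C, wald_dist=self.wald_dist)
        n_tests = self.n_tests if self.n_tests is not None else int(np.isfinite(p).sum())
        thr = bonferroni_threshold(self.alpha, n_tests)
        with np.errstate(divide="ignore", invalid="ignore"):
            nlp = -np.log10(p)
        res = pd.DataFrame(
            {
                "term": self.focal_label,
                "n": nn,
                "beta": beta,
                "se": se,
                "stat": stat,
                "p": p,
                "neg_log10_p": nlp,
                "pass_threshold": nlp >= thr,
                "excluded_reason": reason,
            },
            index=X.columns,
        )
        if snps is not None:
            ann = snps.reindex(X.columns)
            for col in ("chrom", "pos"):
                if col in ann:
                    res.insert(0, col, ann[col])
        self.results_ = res
        self.threshold_ = thr
        self.n_tests_ = n_tests
        self.excluded_ = res.index[res["excluded_reason"] != ""].tolist()
        return self

    def manhattan_table(self) -> pd.DataFrame:
        """(chrom, pos, -log10 p) table for plotting."""
        res = self.results_
        cols = [c for c in ("chrom", "pos") if c in res]
        return res[cols + ["neg_log10_p"]].copy()


class AdmixtureScan(_BaseScan):
    """Admixture mapping: adjusted BP regressed on the local-ancestry code.

    ``n_tests`` should be the effective number of tests from ancestry switches
    (:func:`admixjoint.ancestry.count_ancestry_switches`); it defaults to the
    number of scanned loci, which is conservative.
    """

    focal_label = "local_ancestry"


class AssociationScan(_BaseScan):
    """Association mapping: adjusted BP regressed on the 0/1/2 genotype."""

    focal_label = "genotype"


def admixture_scan(bp_adj, local, samples, snps=None, alpha=0.05,
                   t_adm=None, wald_dist="t") -> AdmixtureScan:
    return AdmixtureScan(alpha=alpha, n_tests=t_adm, wald_dist=wald_dist).fit(
        local, bp_adj, samples=samples, snps=snps
    )


def association_scan(bp_adj, genotypes, samples, snps=None, alpha=0.05,
                     n_tests=None, wald_dist="t") -> AssociationScan:
    return AssociationScan(alpha=alpha, n_tests=n_tests, wald_dist=wald_dist).fit(
        genotypes, bp_adj, samples=samples, snps=snps
    )


def screen_covariates(samples: pd.DataFrame,
                      responses=("sbp_adj", "dbp_adj"),
                      candidates=("age", "sex", "bmi", "education",
                                  "global_ancestry", "ut_self", "ut_other")) -> pd.DataFrame:
    """Univariate screen: simple linear regression of each response on each candidate.

    Mirrors the variable-selection step run before the genome scans; returns a
    table of per-candidate betas, standard errors and p-values.
    """
    rows = []
    for resp in responses:
        if resp not in samples:
            continue
        y = samples[resp]
        for cand in candidates:
            if cand not in samples:
                continue
            x = samples[cand].astype(float)
            keep = y.notna() & x.notna()
            xv = x[keep].to_numpy()
            if np.var(xv) <= 1e-12:
                raise ValueError(f"covariate {cand!r} is constant")
            X = np.column_stack([np.ones(keep.sum()), xv])
            res = fit_ols(y[keep].to_numpy(dtype=float), X, names=["intercept", cand])
            r = res[1]
            rows.append({"response": resp, "covariate": cand, "n": r.n,
                         "beta": r.beta, "se": r.se, "stat": r.stat, "p": r.p})
    return pd.DataFrame(rows)
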