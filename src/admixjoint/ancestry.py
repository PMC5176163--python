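"""Global ancestry, ancestry-switch effective tests, KING kinship, PC-AiR.

Local ancestry arrives as 0/1/2 copies of the target (here: African) ancestry
per individual × SNP, the output convention of LAMP-style callers.  From it we
derive:

* **global ancestry** — the per-individual mean of the 0–2 code divided by 2;
* **the effective number of admixture tests** — the per-individual count of
  local-ancestry switches between adjacent SNPs, summed over autosomes and
  averaged over individuals.  Because ancestry blocks span many SNPs, this is
  far smaller than the SNP count, which is the entire point of admixture
  mapping's reduced multiple-testing burden.

Relatedness is estimated with the KING-robust between-family estimator and a
simplified PC-AiR: partition into a maximal unrelated set, PCA on that set,
projection of relatives onto its axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "global_ancestry",
    "EffectiveTests",
    "count_ancestry_switches",
    "KingKinship",
    "king_kinship",
    "PCAir",
    "pcair",
]


def global_ancestry(local: pd.DataFrame) -> pd.Series:
    """Per-individual global ancestry fraction: mean(0/1/2 code) / 2."""
    if local.shape[1] == 0:
        raise ValueError("local-ancestry matrix has no SNPs")
    return local.mean(axis=1) / 2.0


@dataclass
class EffectiveTests:
    """Effective test counts for the two Bonferroni corrections.

    ``t_adm`` is the mean per-individual ancestry-switch count (the admixture
    testing burden); ``t_assoc`` the number of SNPs tested (the association
    burden).
    """

    t_adm: float
    t_assoc: int
    mode: str = "switches"
    per_individual_switches: pd.Series = field(default=None, repr=False)

    def __post_init__(self):
        if self.t_adm <= 0:
            raise ValueError("t_adm must be positive")
        if self.t_assoc < 1:
            raise ValueError("t_assoc must be >= 1")


def count_ancestry_switches(
    local: pd.DataFrame,
    snps: pd.DataFrame,
    mode: str = "switches",
    t_assoc: int | None = None,
) -> EffectiveTests:
    """Effective number of admixture tests from local-ancestry switch points.

    For each individual and chromosome, counts adjacent-SNP pairs whose 0/1/2
    ancestry code differs; sums over chromosomes and averages over individuals.
    ``mode="switches_plus_chrom"`` additionally counts 1 per chromosome, so a
    switch-free chromosome still contributes one test.

    ``snps`` must contain ``chrom``/``pos`` for every column of ``local`` and
    be sorted by (chrom, pos); SNP order in ``local`` must match.
    """
    if mode not in ("switches", "switches_plus_chrom"):
        raise ValueError(f"unknown mode {mode!r}")
    snps = snps.loc[local.columns]
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    for c in np.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"SNPs on chromosome {c} are not position-sorted")
    codes = local.to_numpy()
    diff = codes[:, 1:] != codes[:, :-1]
    same_chrom = chrom[1:] == chrom[:-1]
    switches = (diff & same_chrom).sum(axis=1).astype(float)
    if mode == "switches_plus_chrom":
        switches += len(np.unique(chrom))
    per_ind = pd.Series(switches, index=local.index, name="n_switches")
    t_adm = float(per_ind.mean())
    return EffectiveTests(
        t_adm=t_adm,
        t_assoc=int(t_assoc if t_assoc is not None else local.shape[1]),
        mode=mode,
        per_individual_switches=per_ind,
    )


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------

class KingKinship(BaseEstimator):
    """KING-robust between-family kinship from 0/1/2 genotypes.

    For a pair (i, j) over SNPs called in both:

        phi_ij = (N_het,het - 2 * N_opposite_homozygote) / (N_het(i) + N_het(j))

    which is robust to population structure and can go negative for pairs from
    different ancestral backgrounds.  The diagonal is set to 0.5 by convention.

    Parameters
    ----------
    min_snps : int, default 100
        Pairs sharing fewer informative SNPs than this are flagged
        low-confidence in ``pairs_``.

    Attributes
    ----------
    kinship_ : pandas.DataFrame, symmetric, diagonal 0.5.
    pairs_ : pandas.DataFrame with id1, id2, n_snps, kinship, low_confidence.
    """

    def __init__(self, min_snps: int = 100):
        self.min_snps = min_snps

    def fit(self, genotypes: pd.DataFrame, y=None):
        if genotypes.shape[0] < 2:
            raise ValueError("kinship needs at least two individuals")
        G = genotypes.to_numpy(dtype=float)
        valid = np.isfinite(G).astype(float)
        het = ((G == 1) & np.isfinite(G)).astype(float)
        homref = ((G == 0) & np.isfinite(G)).astype(float)
        homalt = ((G == 2) & np.isfinite(G)).astype(float)
        n_hethet = het @ het.T
        n_opp = homref @ homalt.T + homalt @ homref.T
        # heterozygote counts of i and j restricted to the pairwise-complete SNPs
        het_i = het @ valid.T
        denom = het_i + het_i.T
        n_shared = valid @ valid.T
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(denom > 0, (n_hethet - 2.0 * n_opp) / denom, np.nan)
        np.fill_diagonal(phi, 0.5)
        ids = genotypes.index
        self.kinship_ = pd.DataFrame(phi, index=ids, columns=ids)
        iu = np.triu_indices(len(ids), k=1)
        self.pairs_ = pd.DataFrame(
            {
                "id1": ids[iu[0]],
                "id2": ids[iu[1]],
                "n_snps": n_shared[iu].astype(int),
                "kinship": phi[iu],
                "low_confidence": n_shared[iu] < self.min_snps,
            }
        )
        return self

    def transform(self, genotypes: pd.DataFrame) -> pd.DataFrame:
        return self.fit(genotypes).kinship_


def king_kinship(genotypes: pd.DataFrame, min_snps: int = 100) -> pd.DataFrame:
    """Pairwise KING-robust kinship matrix (see :class:`KingKinship`)."""
    return KingKinship(min_snps=min_snps).fit(genotypes).kinship_


# ---------------------------------------------------------------------------
# PC-AiR (simplified: partition -> PCA -> projection)
# ---------------------------------------------------------------------------

class PCAir(BaseEstimator):
    """Principal components in the presence of relatedness.

    A deterministic simplification of PC-AiR: (1) greedily build a maximal set
    with all pairwise kinship below ``threshold`` (repeatedly removing the
    individual with most remaining relatives; ties broken by ID sort order,
    the later-sorting individual removed); (2) PCA of the unrelated set's
    mean-centred, sqrt(2p(1-p))-standardised genotypes (missing values imputed
    to the per-SNP mean); (3) projection of related individuals onto the
    unrelated-set loadings so every individual receives scores.

    Parameters
    ----------
    threshold : float, default 0.025
        Kinship above or at this value marks a pair as related.
    n_components : int, default 10

    Attributes
    ----------
    scores_ : pandas.DataFrame (individuals × pc1..pcK)
    partition_ : pandas.Series with values {"unrelated", "related"}
    loadings_ : numpy.ndarray (snps × K)
    """

    def __init__(self, threshold: float = 0.025, n_components: int = 10):
        self.threshold = threshold
        self.n_components = n_components

    def fit(self, genotypes: pd.DataFrame, kinship: pd.DataFrame = None, y=None):
        if kinship is None:
            kinship = king_kinship(genotypes)
        kinship = kinship.loc[genotypes.index, genotypes.index]
        unrelated = self._partition(kinship)
        related = [i for i in genotypes.index if i not in set(unrelated)]
        if len(unrelated) <= self.n_components:
            raise ValueError(
                f"only {len(unrelated)} unrelated individuals for "
                f"{self.n_components} components"
            )
        Gu = genotypes.loc[unrelated].to_numpy(dtype=float)
        p = np.nanmean(Gu, axis=0) / 2.0
        scale = np.sqrt(2.0 * p * (1.0 - p))
        informative = scale > 0
        centred = Gu - 2.0 * p
        centred = np.where(np.isfinite(centred), centred, 0.0)  # mean imputation
        Z = centred[:, informative] / scale[informative]
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        k = min(self.n_components, S.size)
        # deterministic sign: largest-magnitude loading positive
        V = Vt[:k].T
        signs = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
        signs[signs == 0] = 1.0
        V = V * signs
        scores_u = Z @ V
        full_scale = np.zeros(genotypes.shape[1])
        full_scale[informative] = 1.0
        loadings = np.zeros((genotypes.shape[1], k))
        loadings[informative] = V
        scores = pd.DataFrame(
            0.0, index=genotypes.index, columns=[f"pc{i+1}" for i in range(k)]
        )
        scores.loc[unrelated] = scores_u
        if related:
            Gr = genotypes.loc[related].to_numpy(dtype=float)
            cr = Gr - 2.0 * p
            cr = np.where(np.isfinite(cr), cr, 0.0)
            Zr = np.zeros_like(cr)
            Zr[:, informative] = cr[:, informative] / scale[informative]
            scores.loc[related] = Zr @ loadings
        self.scores_ = scores
        self.partition_ = pd.Series(
            ["unrelated" if i in set(unrelated) else "related" for i in genotypes.index],
            index=genotypes.index,
            name="partition",
        )
        self.loadings_ = loadings
        self.centre_ = 2.0 * p
        self.scale_ = np.where(informative, scale, 1.0)
        self.unrelated_ = list(unrelated)
        self.related_ = related
        return self

    def _partition(self, kinship: pd.DataFrame) -> list:
        ids = list(kinship.index)
        order = {i: r for r, i in enumerate(sorted(ids, key=str))}
        K = kinship.to_numpy()
        adj = (K >= self.threshold).astype(bool)
        np.fill_diagonal(adj, False)
        alive = np.ones(len(ids), dtype=bool)
        while True:
            deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
            deg[~alive] = 0
            if deg.max() == 0:
                break
            worst = np.flatnonzero(deg == deg.max())
            drop = max(worst, key=lambda i: order[ids[i]])
            alive[drop] = False
        return [ids[i] for i in np.flatnonzero(alive)]

    def transform(self, genotypes: pd.DataFrame) -> pd.DataFrame:
        """Project genotypes onto the fitted axes."""
        G = genotypes.to_numpy(dtype=float)
        c = G - self.centre_
        c = np.where(np.isfinite(c), c, 0.0)
        Z = c / self.scale_
        return pd.DataFrame(
            Z @ self.loadings_, index=genotypes.index, columns=self.scores_.columns
        )


def pcair(genotypes: pd.DataFrame, kinship: pd.DataFrame = None,
          threshold: float = 0.025, n_components: int = 10) -> PCAir:
    """Fit a :class:`PCAir` model and return it."""
    return PCAir(threshold=threshold, n_components=n_components).fit(genotypes, kinship)
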