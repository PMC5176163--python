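"""Cohort data input/output, QC filters, and phenotype construction.

Genotypes are held as a :class:`pandas.DataFrame` of 0/1/2 ALT-allele counts
(individuals in rows, SNPs in columns) with ``NaN`` marking missing calls.
Two on-disk formats are supported: GT-only VCF 4.x and a tab-delimited matrix
(rows = individuals, header = SNP IDs, ``NA`` = missing).  SNP metadata travel
in a parallel DataFrame indexed by SNP ID with ``chrom``, ``pos``, ``ref``,
``alt`` and optional ``closest_gene`` columns.

The QC rules implemented here are the classic array-QC triple — minor allele
frequency, call rate, and an exact Hardy–Weinberg test — applied as *strict*
inequalities (MAF > threshold, call rate > threshold, HWE p > threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_samples",
    "write_samples",
    "average_bp_readings",
    "adjust_bp_for_medication",
    "compute_maf",
    "compute_call_rate",
    "genotype_counts",
    "hwe_exact_test",
    "QCFilter",
    "QCReport",
    "apply_qc",
]

#: mmHg added to the systolic / diastolic reading of medicated individuals.
SBP_MEDICATION_OFFSET = 10.0
DBP_MEDICATION_OFFSET = 5.0

AUTOSOMES = {str(c) for c in range(1, 23)}


# ---------------------------------------------------------------------------
# Reading / writing genotypes
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".vcf", ".vcf.gz")):
        return "vcf"
    return "tsv"


def read_genotypes(path, fmt: str | None = None):
    """Read a genotype matrix and SNP table from VCF or tab-delimited text.

    Parameters
    ----------
    path : str
        Input file.  VCF must carry a GT field; the TSV layout is
        rows = individuals, header = SNP IDs, ``NA`` for missing.
    fmt : {"vcf", "tsv"}, optional
        Force a format; inferred from the extension by default.

    Returns
    -------
    genotypes : pandas.DataFrame
        individuals × SNPs, float 0/1/2 with NaN missing.
    snps : pandas.DataFrame
        indexed by SNP ID; for VCF input has ``chrom``, ``pos``, ``ref``,
        ``alt`` columns.  Non-biallelic and non-autosomal records are skipped
        with a logged reason; half-calls become missing.
    """
    fmt = fmt or _infer_format(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows = []
    meta = []
    seen = set()
    for var in vcf:
        chrom = var.CHROM.removeprefix("chr")
        if chrom not in AUTOSOMES:
            logger.warning("skipping non-autosomal record %s at %s:%d", var.ID, var.CHROM, var.POS)
            continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNP record %s at %s:%d", var.ID, var.CHROM, var.POS)
            continue
        vid = var.ID or f"{chrom}:{var.POS}"
        if vid in seen:
            raise ValueError(f"duplicate SNP ID in VCF: {vid}")
        seen.add(vid)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        codes = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        n_half = sum(1 for g in var.genotypes if (g[0] < 0) != (g[1] < 0))
        if n_half:
            logger.warning("%s: %d half-calls set to missing", vid, n_half)
        snp_ids.append(vid)
        rows.append(codes)
        meta.append((vid, int(chrom), var.POS, var.REF, var.ALT[0]))
    geno = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="individual_id"),
        columns=pd.Index(snp_ids, name="snp_id"),
    )
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "ref", "alt"]).set_index("snp_id")
    _check_unique(geno)
    return geno, snps


def _read_tsv(path):
    geno = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    geno.index.name = "individual_id"
    geno.columns.name = "snp_id"
    geno = geno.astype(float)
    bad = ~(geno.isin([0.0, 1.0, 2.0]) | geno.isna())
    if bad.any().any():
        raise ValueError("tab-delimited genotype matrix contains codes outside {0,1,2,NA}")
    _check_unique(geno)
    snps = pd.DataFrame(index=geno.columns.copy())
    return geno, snps


def _check_unique(geno: pd.DataFrame) -> None:
    if geno.index.duplicated().any():
        raise ValueError("duplicate individual IDs")
    if geno.columns.duplicated().any():
        raise ValueError("duplicate SNP IDs")


def write_genotypes_tsv(path, genotypes: pd.DataFrame) -> None:
    """Write the genotype matrix as TSV (NA = missing, integer codes)."""
    out = genotypes.copy()
    with open(path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(map(str, out.columns)) + "\n")
        for ind, row in out.iterrows():
            vals = ["NA" if not np.isfinite(v) else str(int(v)) for v in row.to_numpy()]
            fh.write(str(ind) + "\t" + "\t".join(vals) + "\n")


def write_genotypes_vcf(path, genotypes: pd.DataFrame, snps: pd.DataFrame) -> None:
    """Write a minimal GT-only VCF 4.2 file.

    ``snps`` must provide ``chrom``/``pos``/``ref``/``alt`` for every column of
    ``genotypes``; unphased diploid GT codes are emitted (``./.`` for missing).
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted({int(snps.loc[s, "chrom"]) for s in genotypes.columns}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.index))
            + "\n"
        )
        mat = genotypes.to_numpy()
        for j, sid in enumerate(genotypes.columns):
            rec = snps.loc[sid]
            calls = [
                "./." if not np.isfinite(v) else gt_map[int(v)] for v in mat[:, j]
            ]
            fh.write(
                f"{int(rec['chrom'])}\t{int(rec['pos'])}\t{sid}\t{rec['ref']}\t{rec['alt']}"
                "\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_samples(path) -> pd.DataFrame:
    """Read the per-individual sample table (CSV, indexed by individual_id)."""
    df = pd.read_csv(path, index_col="individual_id")
    if "med_flag" in df:
        df["med_flag"] = df["med_flag"].astype(bool)
    return df


def write_samples(path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, index_label="individual_id")


# ---------------------------------------------------------------------------
# Phenotype construction
# ---------------------------------------------------------------------------

def average_bp_readings(readings) -> float:
    """Mean of the last two of exactly three ordered BP readings.

    The first of the three resting readings is systematically elevated and is
    discarded; the analysis phenotype is the mean of readings two and three.
    """
    readings = list(readings)
    if len(readings) != 3:
        raise ValueError(f"expected exactly 3 readings, got {len(readings)}")
    return (readings[1] + readings[2]) / 2.0


def adjust_bp_for_medication(
    samples: pd.DataFrame,
    sbp_offset: float = SBP_MEDICATION_OFFSET,
    dbp_offset: float = DBP_MEDICATION_OFFSET,
) -> pd.DataFrame:
    """Populate ``sbp_adj``/``dbp_adj`` from raw readings and the medication flag.

    Antihypertensive treatment is handled by adding a fixed offset
    (10 mmHg systolic, 5 mmHg diastolic) to the readings of medicated
    individuals rather than by a treatment covariate; unmedicated rows pass
    through unchanged.
    """
    if "med_flag" not in samples:
        raise ValueError("sample table lacks 'med_flag'")
    out = samples.copy()
    med = out["med_flag"].astype(float)
    if "sbp_raw" in out:
        out["sbp_adj"] = out["sbp_raw"] + sbp_offset * med
    if "dbp_raw" in out:
        out["dbp_adj"] = out["dbp_raw"] + dbp_offset * med
    return out


# ---------------------------------------------------------------------------
# Per-SNP metrics
# ---------------------------------------------------------------------------

def compute_maf(column) -> float:
    """Minor allele frequency of one SNP over non-missing calls, folded to ≤0.5."""
    x = np.asarray(column, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    p = x.sum() / (2.0 * x.size)
    return min(p, 1.0 - p)


def compute_call_rate(column) -> float:
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("empty genotype column")
    return float(np.isfinite(x).mean())


def genotype_counts(column) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts over non-missing calls."""
    x = np.asarray(column, dtype=float)
    x = x[np.isfinite(x)]
    return int((x == 0).sum()), int((x == 1).sum()), int((x == 2).sum())


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int, midp: bool = False) -> float:
    """Exact test of Hardy–Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts that are no more probable than the observed one (the
    standard two-sided exact HWE test).  With ``midp`` only half the observed
    configuration's probability is included.

    Returns the p-value; monomorphic sites return 1.0 (a single feasible
    configuration).
    """
    for c in (n_homref, n_het, n_homalt):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_homref, n_homalt) + n_het  # minor allele count
    # Feasible heterozygote counts share the parity of the minor allele count.
    hets = range(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | allele counts) up to a common constant:
    #   P(h) ∝ n_rare! n_common! n! 2^h / ( ((n_rare-h)/2)! h! ((n_common-h)/2)! ... )
    logps = []
    for h in hets:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            continue
        lp = (
            h * math.log(2.0)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(common_hom + 1)
        )
        logps.append((h, lp))
    lps = np.array([lp for _, lp in logps])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs = [i for i, (h, _) in enumerate(logps) if h == n_het]
    if not obs:
        raise ValueError("observed heterozygote count infeasible for allele counts")
    p_obs = probs[obs[0]]
    mask = probs <= p_obs * (1.0 + 1e-12)
    p = float(probs[mask].sum())
    if midp:
        p -= 0.5 * float(p_obs)
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-rule removal counts from one QC pass."""

    n_input: int = 0
    n_fail_maf: int = 0
    n_fail_call: int = 0
    n_fail_hwe: int = 0
    n_pass: int = 0
    failed_snps: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "maf", "call_rate", "hwe", "pass"],
                "count": [self.n_input, self.n_fail_maf, self.n_fail_call, self.n_fail_hwe, self.n_pass],
            }
        )


class QCFilter(BaseEstimator):
    """SNP quality-control filter (MAF, call rate, exact HWE).

    All three thresholds are strict inequalities, matching the usual printed
    form of the rules: a SNP survives iff MAF > ``maf_min`` AND
    call rate > ``call_min`` AND HWE p > ``hwe_min``.

    Parameters
    ----------
    maf_min : float, default 0.01
    call_min : float, default 0.95
    hwe_min : float, default 0.001
    hwe_midp : bool, default False
        Use the mid-p variant of the exact HWE test.

    Attributes
    ----------
    metrics_ : pandas.DataFrame
        Per-SNP ``maf``, ``call_rate``, ``hwe_p`` and ``pass_qc``.
    report_ : QCReport
    keep_ : pandas.Index of surviving SNP IDs.
    """

    def __init__(self, maf_min: float = 0.01, call_min: float = 0.95,
                 hwe_min: float = 0.001, hwe_midp: bool = False):
        self.maf_min = maf_min
        self.call_min = call_min
        self.hwe_min = hwe_min
        self.hwe_midp = hwe_midp

    def fit(self, genotypes: pd.DataFrame, y=None):
        for name in ("maf_min", "call_min", "hwe_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        mat = genotypes.to_numpy(dtype=float)
        n_ind = mat.shape[0]
        finite = np.isfinite(mat)
        n_called = finite.sum(axis=0)
        if (n_called == 0).any():
            bad = genotypes.columns[n_called == 0].tolist()
            raise ValueError(f"SNPs with no called genotypes: {bad[:5]}")
        alt = np.where(finite, mat, 0.0).sum(axis=0)
        p = alt / (2.0 * n_called)
        maf = np.minimum(p, 1.0 - p)
        call_rate = n_called / float(n_ind)
        hwe_p = np.empty(mat.shape[1])
        for j in range(mat.shape[1]):
            col = mat[finite[:, j], j]
            hwe_p[j] = hwe_exact_test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()),
                midp=self.hwe_midp,
            )
        ok_maf = maf > self.maf_min
        ok_call = call_rate > self.call_min
        ok_hwe = hwe_p > self.hwe_min
        ok = ok_maf & ok_call & ok_hwe
        self.metrics_ = pd.DataFrame(
            {"maf": maf, "call_rate": call_rate, "hwe_p": hwe_p, "pass_qc": ok},
            index=genotypes.columns,
        )
        self.report_ = QCReport(
            n_input=mat.shape[1],
            n_fail_maf=int((~ok_maf).sum()),
            n_fail_call=int((~ok_call).sum()),
            n_fail_hwe=int((~ok_hwe).sum()),
            n_pass=int(ok.sum()),
            failed_snps={
                str(s): ";".join(
                    r for r, bad in (("maf", not m), ("call_rate", not c), ("hwe", not h)) if bad
                )
                for s, m, c, h in zip(genotypes.columns, ok_maf, ok_call, ok_hwe)
                if not (m and c and h)
            },
        )
        self.keep_ = genotypes.columns[ok]
        return self

    def transform(self, genotypes: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "keep_"):
            raise RuntimeError("QCFilter must be fitted before transform")
        return genotypes.loc[:, genotypes.columns.intersection(self.keep_)]

    def fit_transform(self, genotypes: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(genotypes).transform(genotypes)


def apply_qc(genotypes: pd.DataFrame, snps: pd.DataFrame | None = None,
             maf_min: float = 0.01, call_min: float = 0.95, hwe_min: float = 0.001,
             hwe_midp: bool = False):
    """Functional wrapper around :class:`QCFilter`.

    Returns (filtered genotypes, filtered+annotated SNP table, QCReport).
    """
    qc = QCFilter(maf_min=maf_min, call_min=call_min, hwe_min=hwe_min, hwe_midp=hwe_midp)
    filtered = qc.fit_transform(genotypes)
    if snps is None:
        snps = pd.DataFrame(index=genotypes.columns.copy())
    snps_out = snps.join(qc.metrics_[["maf", "call_rate", "hwe_p"]], how="left")
    snps_out = snps_out.loc[filtered.columns]
    for sid, reason in qc.report_.failed_snps.items():
        logger.info("QC removed %s (%s)", sid, reason)
    return filtered, snps_out, qc.report_
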