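"""End-to-end pipeline: QC → ancestry/kinship/PCs → scans → joint models → permutation.

The pipeline is driven by a :class:`PipelineConfig` (loadable from YAML) and
produces a :class:`PipelineResult` bundle plus, optionally, a directory of
TSV/CSV/JSON reports: QC report, effective-test counts, kinship pairs, PC
scores, frequentist scan tables, joint-model tables with the ≥0.5 hits, and
the permutation-confirmation table.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from .ancestry import KingKinship, PCAir, count_ancestry_switches, global_ancestry
from .joint import JointAdmixtureAssociation
from .permutation import PermutationConfirmation
from .scan import AdmixtureScan, AssociationScan, screen_covariates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report_tables",
           "load_config"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``models`` is a list of (model, ut_variable, ut_coding) triples, e.g.
    ``[(1, None, "count"), (3, "ut_other", "no_yes")]``.
    """

    genotypes: str = None
    local_ancestry: str = None
    samples: str = None
    annotation: str = None
    genotype_format: str = None      # inferred from extension when None
    aims_file: str = None            # optional SNP-ID exclusion list
    response: str = "both"           # sbp | dbp | both
    models: list = field(default_factory=lambda: [(1, None, "count")])
    # QC thresholds (strict inequalities)
    maf_min: float = 0.01
    call_min: float = 0.95
    hwe_min: float = 0.001
    hwe_midp: bool = False
    # kinship / PCs
    kinship_threshold: float = 0.025
    n_pcs: int = 10
    pca_maf_min: float = 0.05
    # thresholds / Bayes
    alpha: float = 0.05
    switch_mode: str = "switches"
    prior_effect_sd: float = 0.2
    pi_mode: str = "one_over_t_adm"
    min_stratum_n: int = 10
    maf_min_model3: float = 0.10
    wald_dist: str = "t"
    # permutation
    n_perm: int = 10_000
    perm_seed: int = 385
    recompute_prior: bool = True
    # misc
    out_dir: str = None
    seed: int = 0

    def __post_init__(self):
        if not self.models:
            raise ValueError("config error at 'models': at least one model required")
        norm = []
        for entry in self.models:
            m, ut, coding = (list(entry) + [None, "count"])[:3] if len(entry) < 3 else entry
            m = int(m)
            if m not in (1, 2, 3):
                raise ValueError(f"config error at 'models': model must be 1/2/3, got {m}")
            if m >= 2 and ut not in ("ut_self", "ut_other"):
                raise ValueError(
                    f"config error at 'models': model {m} requires ut_self or ut_other"
                )
            coding = coding or "count"
            if coding not in ("count", "no_yes", "low_high"):
                raise ValueError(f"config error at 'models': unknown ut_coding {coding!r}")
            norm.append((m, ut if m >= 2 else None, coding if m >= 2 else "count"))
        self.models = norm
        if self.response not in ("sbp", "dbp", "both"):
            raise ValueError("config error at 'response': must be sbp, dbp or both")

    @property
    def responses(self) -> list:
        return ["sbp", "dbp"] if self.response == "both" else [self.response]


def load_config(path) -> PipelineConfig:
    """Load a YAML config file into a :class:`PipelineConfig`."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    models = raw.pop("models", None)
    cfg = PipelineConfig(**raw) if models is None else PipelineConfig(models=models, **raw)
    return cfg


@dataclass
class PipelineResult:
    """Everything one run produced, keyed the way the reports are written."""

    samples: pd.DataFrame
    snps: pd.DataFrame
    qc_report: cio.QCReport
    effective_tests: object
    kinship: pd.DataFrame
    pc_partition: pd.Series
    covariate_screen: pd.DataFrame
    scans: dict          # (response, kind) -> scan estimator
    joint: dict          # (response, model, ut, coding) -> JointAdmixtureAssociation
    confirmations: dict  # (response, model, ut, coding) -> DataFrame
    log: list


def run_pipeline(config: PipelineConfig, data: dict = None) -> PipelineResult:
    """Execute the full analysis.

    ``data`` may supply in-memory inputs (keys ``genotypes``, ``snps``,
    ``local_ancestry``, ``samples``) instead of the config's file paths — the
    route the simulator and the test-suite use.
    """
    log: list[str] = []

    def note(msg, *args):
        logger.info(msg, *args)
        log.append(msg % args if args else msg)

    # ------------------------------------------------ load
    if data is not None:
        genotypes = data["genotypes"].copy()
        snps = data.get("snps")
        local = data["local_ancestry"].copy()
        samples = data["samples"].copy()
    else:
        genotypes, snps = cio.read_genotypes(config.genotypes, config.genotype_format)
        local = pd.read_csv(config.local_ancestry, sep="\t", index_col=0)
        local.index.name = "individual_id"
        local.columns.name = "snp_id"
        samples = cio.read_samples(config.samples)
    if snps is None or snps.empty:
        snps = pd.DataFrame(index=genotypes.columns.copy())
    if config.annotation:
        ann = pd.read_csv(config.annotation, sep="\t", index_col="snp_id")
        snps = snps.drop(columns=[c for c in ann.columns if c in snps.columns]).join(ann)
    ids = genotypes.index.intersection(samples.index).intersection(local.index)
    genotypes, local, samples = genotypes.loc[ids], local.loc[ids], samples.loc[ids]
    note("loaded %d individuals x %d SNPs", genotypes.shape[0], genotypes.shape[1])

    if config.aims_file:
        with open(config.aims_file) as fh:
            aims = {line.strip() for line in fh if line.strip()}
        keep = [c for c in genotypes.columns if c not in aims]
        note("AIMs exclusion list removed %d SNPs", genotypes.shape[1] - len(keep))
        genotypes = genotypes[keep]

    # ------------------------------------------------ phenotype construction
    samples = cio.adjust_bp_for_medication(samples)

    # ------------------------------------------------ QC
    genotypes, snps_qc, qc_report = cio.apply_qc(
        genotypes, snps, maf_min=config.maf_min, call_min=config.call_min,
        hwe_min=config.hwe_min, hwe_midp=config.hwe_midp,
    )
    local = local[genotypes.columns]
    note("QC: %d/%d SNPs pass (maf fail %d, call fail %d, hwe fail %d)",
         qc_report.n_pass, qc_report.n_input, qc_report.n_fail_maf,
         qc_report.n_fail_call, qc_report.n_fail_hwe)

    # ------------------------------------------------ ancestry, kinship, PCs
    samples["global_ancestry"] = global_ancestry(local)
    eff = count_ancestry_switches(local, snps_qc, mode=config.switch_mode)
    note("effective tests: t_adm=%.2f, t_assoc=%d", eff.t_adm, eff.t_assoc)

    king = KingKinship().fit(genotypes)
    pca_cols = [c for c in genotypes.columns
                if cio.compute_maf(genotypes[c]) >= config.pca_maf_min]
    pca = PCAir(threshold=config.kinship_threshold, n_components=config.n_pcs).fit(
        genotypes[pca_cols] if pca_cols else genotypes, king.kinship_
    )
    for c in pca.scores_.columns:
        samples[c] = pca.scores_[c]
    note("PC-AiR: %d unrelated / %d related at kinship >= %g",
         len(pca.unrelated_), len(pca.related_), config.kinship_threshold)

    screen = screen_covariates(samples)

    # ------------------------------------------------ frequentist scans
    scans = {}
    for resp in config.responses:
        y = samples[f"{resp}_adj"]
        scans[(resp, "admixture")] = AdmixtureScan(
            alpha=config.alpha, n_tests=eff.t_adm, wald_dist=config.wald_dist
        ).fit(local, y, samples=samples, snps=snps_qc)
        scans[(resp, "association")] = AssociationScan(
            alpha=config.alpha, n_tests=eff.t_assoc, wald_dist=config.wald_dist
        ).fit(genotypes, y, samples=samples, snps=snps_qc)
        for kind in ("admixture", "association"):
            sc = scans[(resp, kind)]
            note("%s scan (%s): %d hits above -log10 threshold %.2f, %d excluded",
                 kind, resp, int(sc.results_["pass_threshold"].sum()),
                 sc.threshold_, len(sc.excluded_))

    # ------------------------------------------------ joint models
    joint = {}
    confirmations = {}
    for resp in config.responses:
        y = samples[f"{resp}_adj"]
        for (m, ut, coding) in config.models:
            est = JointAdmixtureAssociation(
                model=m, ut_variable=ut, ut_coding=coding,
                prior_effect_sd=config.prior_effect_sd, pi_mode=config.pi_mode,
                min_stratum_n=config.min_stratum_n,
                maf_min_model3=config.maf_min_model3, wald_dist=config.wald_dist,
            ).fit(genotypes, y, local_ancestry=local, samples=samples,
                  effective_tests=eff, snps=snps_qc)
            joint[(resp, m, ut, coding)] = est
            n_excl = int((est.results_["excluded_reason"] != "").sum())
            note("joint model %d (%s, ut=%s/%s): %d hits, %d SNPs excluded",
                 m, resp, ut, coding, len(est.hits_), n_excl)
            if config.n_perm > 0 and len(est.hits_) > 0:
                pc = PermutationConfirmation(
                    n_perm=config.n_perm, alpha=config.alpha,
                    seed=config.perm_seed, recompute_prior=config.recompute_prior,
                ).fit(est.hits_, estimator=est, genotypes=genotypes,
                      local_ancestry=local, samples=samples,
                      response=f"{resp}_adj", effective_tests=eff, snps=snps_qc)
                confirmations[(resp, m, ut, coding)] = pc.results_
                note("permutation (%s model %d): %d/%d hits confirmed",
                     resp, m, int(pc.results_["confirmed"].sum()), len(pc.results_))

    result = PipelineResult(
        samples=samples, snps=snps_qc, qc_report=qc_report, effective_tests=eff,
        kinship=king.pairs_, pc_partition=pca.partition_, covariate_screen=screen,
        scans=scans, joint=joint, confirmations=confirmations, log=log,
    )
    if config.out_dir:
        report_tables(result, config.out_dir)
    return result


def _fmt_posterior(p: float) -> str:
    """Tables-2/3 display convention: two decimals, capped at 1.00."""
    return f"{min(p, 1.0):.2f}"


def report_tables(result: PipelineResult, out_dir) -> dict:
    """Write the result bundle as TSV/CSV/JSON reports; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    p = os.path.join(out_dir, "qc_report.tsv")
    result.qc_report.to_frame().to_csv(p, sep="\t", index=False)
    paths["qc_report"] = p

    p = os.path.join(out_dir, "effective_tests.json")
    eff = result.effective_tests
    with open(p, "w") as fh:
        json.dump({"t_adm": eff.t_adm, "t_assoc": eff.t_assoc, "mode": eff.mode}, fh, indent=2)
    paths["effective_tests"] = p

    p = os.path.join(out_dir, "kinship.tsv")
    result.kinship.to_csv(p, sep="\t", index=False)
    paths["kinship"] = p

    p = os.path.join(out_dir, "pc_scores.csv")
    pc_cols = [c for c in result.samples.columns if c.startswith("pc")]
    scores = result.samples[pc_cols].copy()
    scores["partition"] = result.pc_partition
    scores.to_csv(p, index_label="individual_id")
    paths["pc_scores"] = p

    p = os.path.join(out_dir, "covariate_screen.tsv")
    result.covariate_screen.to_csv(p, sep="\t", index=False)
    paths["covariate_screen"] = p

    for (resp, kind), sc in result.scans.items():
        p = os.path.join(out_dir, f"scan_{kind}_{resp}.tsv")
        sc.results_.to_csv(p, sep="\t", index_label="snp_id")
        paths[f"scan_{kind}_{resp}"] = p
        p = os.path.join(out_dir, f"manhattan_{kind}_{resp}.tsv")
        sc.manhattan_table().to_csv(p, sep="\t", index_label="snp_id")

    sig_rows = []
    for (resp, m, ut, coding), est in result.joint.items():
        tag = f"model{m}_{ut or 'none'}_{coding}_{resp}"
        p = os.path.join(out_dir, f"joint_{tag}.tsv")
        est.results_.to_csv(p, sep="\t", index_label="snp_id")
        paths[f"joint_{tag}"] = p
        p = os.path.join(out_dir, f"manhattan_joint_{tag}.tsv")
        est.manhattan_table().to_csv(p, sep="\t", index_label="snp_id")
        conf = result.confirmations.get((resp, m, ut, coding))
        for sid, row in est.hits_.iterrows():
            confirmed = ""
            if conf is not None and sid in conf.index:
                confirmed = bool(conf.loc[sid, "confirmed"])
            sig_rows.append({
                "response": resp,
                "model": m,
                "ut_variable": ut or "N/A",
                "ut_coding": coding if m >= 2 else "N/A",
                "snp_id": sid,
                "chrom": row.get("chrom", ""),
                "closest_gene": row.get("closest_gene", ""),
                "joint_posterior": _fmt_posterior(row["joint_posterior"]),
                "confirmed": confirmed,
            })
    p = os.path.join(out_dir, "significant_hits.tsv")
    cols = ["response", "model", "ut_variable", "ut_coding", "snp_id", "chrom",
            "closest_gene", "joint_posterior", "confirmed"]
    pd.DataFrame(sig_rows, columns=cols).to_csv(p, sep="\t", index=False)
    paths["significant_hits"] = p

    for (key), conf in result.confirmations.items():
        resp, m, ut, coding = key
        p = os.path.join(out_dir, f"confirmation_model{m}_{ut or 'none'}_{coding}_{resp}.tsv")
        conf.to_csv(p, sep="\t", index_label="snp_id")

    p = os.path.join(out_dir, "run_log.txt")
    with open(p, "w") as fh:
        fh.write("\n".join(result.log) + "\n")
    paths["run_log"] = p
    return paths
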