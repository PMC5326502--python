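"""End-to-end work flow: pileup -> QC filters -> RM bias -> RAF -> posterior calls.

The QC report accounts for every input SNP exactly once:
input = kept + sum(removed per stage).  Replicate-consistency masking acts
within experiments and does not itself remove SNPs; SNPs it empties are
removed by the unique-allele stage as "no data".
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .filters import (
    ExactMatchAligner,
    RemovalLog,
    filter_regions,
    intrinsic_bias_filter,
    replicate_consistency_filter,
    unique_allele_filter,
)
from .model import MCMCSettings, SNPModelInput, call_asb, hpd_interval, sample_posterior_batch
from .pileup import SampleAlignments, pileup_counts, pileup_sample
from .raf import assign_raf
from .rmbias import estimate_rm_bias
from .types import AlleleCountTable, HetSNP

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "call_snps"]

RESULT_COLUMNS = [
    "snp_id",
    "n_samples",
    "pooled_a",
    "pooled_d",
    "raf",
    "rm_bias",
    "posterior_mean",
    "hpd_lower",
    "hpd_upper",
    "call",
]


def call_snps(
    table: AlleleCountTable,
    snps: list[HetSNP],
    hp=None,
    mcmc: MCMCSettings | None = None,
) -> pd.DataFrame:
    """Per-SNP posterior inference on a QC-passing count table.

    Each SNP needs a RAF (rho) and an RM bias (mu) annotation; all chains run
    in lockstep for speed.  Returns the per-SNP result table.
    """
    from .model import ModelHyperParams

    hp = hp or ModelHyperParams()
    mcmc = mcmc or MCMCSettings()
    by_id = {s.id: s for s in snps}
    usable = [
        s_id
        for s_id in table.snp_ids
        if s_id in by_id
        and by_id[s_id].raf is not None
        and by_id[s_id].rm_bias is not None
        and table.pooled(s_id)[1] > 0
    ]
    if not usable:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    n_cols = len(table.sample_ids)
    K = len(usable)
    a = np.zeros((K, n_cols))
    d = np.zeros((K, n_cols))
    mask = np.zeros((K, n_cols), dtype=bool)
    for k, snp_id in enumerate(usable):
        for j, s in enumerate(table.sample_ids):
            if not table.is_missing(snp_id, s):
                a[k, j] = table.ref.at[snp_id, s]
                d[k, j] = table.total.at[snp_id, s]
                mask[k, j] = True
    rho = np.array([by_id[s_id].raf for s_id in usable])
    mu = np.array([by_id[s_id].rm_bias for s_id in usable])
    traces, _ = sample_posterior_batch(a, d, rho, mu, hp=hp, mcmc=mcmc, mask=mask)

    rows = []
    for k, snp_id in enumerate(usable):
        lo, hi = hpd_interval(traces[k], hp.hpd_mass)
        pooled_a, pooled_d = table.pooled(snp_id)
        rows.append(
            {
                "snp_id": snp_id,
                "n_samples": int(mask[k].sum()),
                "pooled_a": pooled_a,
                "pooled_d": pooled_d,
                "raf": by_id[snp_id].raf,
                "rm_bias": by_id[snp_id].rm_bias,
                "posterior_mean": float(traces[k].mean()),
                "hpd_lower": lo,
                "hpd_upper": hi,
                "call": call_asb((lo, hi), hp.exclusion_zone),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_pipeline(cfg: aio.RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full work flow and write results under cfg.output_dir.

    Returns (result table, QC report).  Per-SNP model failures are logged
    and recorded, not fatal; configuration errors fail fast.
    """
    cfg.validate_paths()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    snps = aio.read_snp_table(cfg.snp_table)
    n_input = len(snps)
    logs: list[RemovalLog] = []

    region_sets = [aio.read_bed(p) for p in cfg.region_sets]
    snps, log_regions = filter_regions(snps, region_sets)
    logs.append(log_regions)

    if cfg.genome_fasta:
        genome = aio.load_fasta(cfg.genome_fasta)
        snps, log_bias = intrinsic_bias_filter(
            snps, genome, ExactMatchAligner(), cfg.read_length
        )
        logs.append(log_bias)

    sample_alignments = [
        SampleAlignments(s.sample_id, s.bam, aio.read_bed(s.bed) if s.bed else None)
        for s in cfg.samples
    ]
    table = pileup_counts(
        sample_alignments, snps, cfg.replicate_groups, cfg.min_mapq, cfg.min_baseq
    )
    table, log_rep = replicate_consistency_filter(table)
    table, log_unique = unique_allele_filter(table)
    logs.append(log_unique)
    snps = [s for s in snps if s.id in set(table.snp_ids)]

    results = pd.DataFrame(columns=RESULT_COLUMNS)
    no_raf_log = RemovalLog("no_raf", [])
    if snps:
        estimate_rm_bias(table, snps, cfg.min_sites)

        gdna_counts: dict[str, tuple[int, int]] = {}
        gdna_bams = [s.gdna_bam for s in cfg.samples if s.gdna_bam]
        for bam in dict.fromkeys(gdna_bams):
            per_snp = pileup_sample(bam, snps, None, cfg.min_mapq, cfg.min_baseq)
            for snp_id, (a, d, _) in per_snp.items():
                a0, d0 = gdna_counts.get(snp_id, (0, 0))
                gdna_counts[snp_id] = (a0 + a, d0 + d)
        baf_records = aio.read_baf_table(cfg.baf_table) if cfg.baf_table else None
        unassigned = assign_raf(snps, baf_records, gdna_counts or None, cfg.min_cov)
        if unassigned:
            no_raf_log = RemovalLog("no_raf", [(i, "no usable RAF source") for i in unassigned])
            drop = set(unassigned)
            snps = [s for s in snps if s.id not in drop]
            table = table.subset([i for i in table.snp_ids if i not in drop])
        results = call_snps(table, snps, cfg.hyperparams, cfg.mcmc)
    logs.append(no_raf_log)

    report = {
        "input_snps": n_input,
        "removed": {log.filter_name: len(log.removed_ids) for log in logs},
        "replicate_masked_cells": len(log_rep.removed),
        "kept_snps": len(results),
        "seed": cfg.seed,
        "mcmc": {
            "n_iter": cfg.mcmc.n_iter,
            "burn_in": cfg.mcmc.burn_in,
            "proposal_sd": cfg.mcmc.proposal_sd,
            "seed": cfg.mcmc.seed,
        },
        "thresholds": {
            "min_mapq": cfg.min_mapq,
            "min_baseq": cfg.min_baseq,
            "min_sites": cfg.min_sites,
            "min_cov": cfg.min_cov,
        },
    }
    assert report["input_snps"] == report["kept_snps"] + sum(report["removed"].values())

    aio.write_counts_table(table, snps, out_dir / "counts.tsv")
    aio.write_results(results, out_dir / "results.tsv")
    aio.write_removal_logs(logs + [log_rep], out_dir / "removal_logs.tsv")
    (out_dir / "qc_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return results, report
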