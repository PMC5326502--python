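"""File formats and run configuration.

Conventions: SNP tables are 1-based TSV (ID/CHROM/POS/REF/ALT, optional
RAF); BED files and region sets are 0-based half-open; all emitted tables
are plain TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .model import MCMCSettings, ModelHyperParams
from .types import AlleleCountTable, HetSNP, RegionSet

__all__ = [
    "read_snp_table",
    "write_snp_table",
    "read_bed",
    "write_bed",
    "read_baf_table",
    "load_fasta",
    "write_fasta",
    "write_counts_table",
    "read_counts_table",
    "write_results",
    "write_removal_logs",
    "SampleSpec",
    "RunConfig",
    "load_run_config",
]

_SNP_COLUMNS = ("ID", "CHROM", "POS", "REF", "ALT")


def read_snp_table(path: str | Path) -> list[HetSNP]:
    """Read the tab-delimited het-SNP table (header ID/CHROM/POS/REF/ALT[/RAF])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    snps: list[HetSNP] = []
    seen: set[str] = set()
    has_raf = "RAF" in df.columns
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        snp_id = row["ID"]
        if snp_id in seen:
            raise ValueError(f"{path}:{line}: duplicate SNP id {snp_id!r}")
        seen.add(snp_id)
        try:
            raf = None
            if has_raf and isinstance(row["RAF"], str) and row["RAF"].strip() not in ("", "NA"):
                raf = float(row["RAF"])
            snps.append(
                HetSNP(
                    id=snp_id,
                    chrom=row["CHROM"],
                    pos=int(row["POS"]),
                    ref=row["REF"],
                    alt=row["ALT"],
                    raf=raf,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{line}: {exc}") from exc
    return snps


def write_snp_table(snps: Sequence[HetSNP], path: str | Path) -> None:
    rows = [
        {
            "ID": s.id,
            "CHROM": s.chrom,
            "POS": s.pos,
            "REF": s.ref,
            "ALT": s.alt,
            "RAF": "" if s.raf is None else s.raf,
        }
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED file (>= 3 columns, 0-based half-open) into a RegionSet."""
    rs = RegionSet(name or Path(path).stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            rs.add(fields[0], start, end)
    return rs


def write_bed(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in rs.chroms():
            for start, end in rs.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_baf_table(path: str | Path):
    """Read a BAF TSV (ID, BAF, ALLELE_A, ALLELE_B) into {id: BAFRecord}."""
    from .raf import BAFRecord

    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "ALLELE_A": str, "ALLELE_B": str})
    out = {}
    for _, row in df.iterrows():
        baf = row["BAF"]
        out[row["ID"]] = BAFRecord(
            snp_id=row["ID"],
            baf=None if pd.isna(baf) else float(baf),
            allele_a=row["ALLELE_A"],
            allele_b=row["ALLELE_B"],
        )
    return out


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a (toy-scale) FASTA into {chrom: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_counts_table(table: AlleleCountTable, snps: Sequence[HetSNP], path: str | Path) -> None:
    """Write the merged counts table: per-sample a/d columns plus RM, RAF, Peak."""
    by_id = {s.id: s for s in snps}
    rows = []
    for snp_id in table.snp_ids:
        snp = by_id.get(snp_id)
        row: dict[str, object] = {"ID": snp_id}
        for s in table.sample_ids:
            missing = table.is_missing(snp_id, s)
            row[f"{s}.a"] = "NA" if missing else int(table.ref.at[snp_id, s])
            row[f"{s}.d"] = "NA" if missing else int(table.total.at[snp_id, s])
            row[f"{s}.peak"] = int(bool(table.peak.at[snp_id, s]))
        row["RM"] = "NA" if snp is None or snp.rm_bias is None else snp.rm_bias
        row["RAF"] = "NA" if snp is None or snp.raf is None else snp.raf
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path) -> tuple[AlleleCountTable, pd.DataFrame]:
    """Read a counts table written by write_counts_table.

    Returns the count table and the full DataFrame (with RM/RAF columns).
    """
    import numpy as np

    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"ID": str}).set_index("ID")
    samples = sorted({c[:-2] for c in df.columns if c.endswith(".a")})
    ref = df[[f"{s}.a" for s in samples]].copy()
    ref.columns = samples
    total = df[[f"{s}.d" for s in samples]].copy()
    total.columns = samples
    peak = df[[f"{s}.peak" for s in samples]].fillna(0).astype(bool)
    peak.columns = samples
    return AlleleCountTable(ref, total, peak), df


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_removal_logs(logs, path: str | Path) -> None:
    rows = [
        {"filter": log.filter_name, "snp_id": snp_id, "reason": reason}
        for log in logs
        for snp_id, reason in log.removed
    ]
    pd.DataFrame(rows, columns=["filter", "snp_id", "reason"]).to_csv(path, sep="\t", index=False)


@dataclass
class SampleSpec:
    """One sample of the run: experiment/TF, replicate, alignment and peak files."""

    sample_id: str
    experiment: str
    replicate: str
    bam: str
    bed: str | None = None
    gdna_bam: str | None = None


@dataclass
class RunConfig:
    """Validated end-to-end run configuration (YAML-loadable)."""

    samples: list[SampleSpec]
    snp_table: str
    region_sets: list[str] = field(default_factory=list)
    baf_table: str | None = None
    genome_fasta: str | None = None
    read_length: int = 36
    min_mapq: int = 15
    min_baseq: int = 10
    min_sites: int = 200
    min_cov: int = 10
    hyperparams: ModelHyperParams = field(default_factory=ModelHyperParams)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int = 0
    output_dir: str = "asbcall_out"

    def __post_init__(self) -> None:
        keys = [(s.experiment, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("replicate ids must be unique within each experiment")

    @property
    def replicate_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for s in self.samples:
            groups.setdefault(s.experiment, []).append(s.sample_id)
        return groups

    def validate_paths(self) -> None:
        paths = [self.snp_table, *self.region_sets]
        if self.baf_table:
            paths.append(self.baf_table)
        if self.genome_fasta:
            paths.append(self.genome_fasta)
        for s in self.samples:
            paths.append(s.bam)
            if s.bed:
                paths.append(s.bed)
            if s.gdna_bam:
                paths.append(s.gdna_bam)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    samples = [SampleSpec(**s) for s in raw.pop("samples")]
    hp_raw = raw.pop("hyperparams", {})
    if "exclusion_zone" in hp_raw:
        hp_raw["exclusion_zone"] = tuple(hp_raw["exclusion_zone"])
    mcmc_raw = raw.pop("mcmc", {})
    cfg = RunConfig(
        samples=samples,
        hyperparams=ModelHyperParams(**hp_raw),
        mcmc=MCMCSettings(**mcmc_raw),
        **raw,
    )
    base = Path(path).parent
    # resolve relative paths against the config file location
    def _resolve(p: str | None) -> str | None:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    cfg.snp_table = _resolve(cfg.snp_table)
    cfg.region_sets = [_resolve(p) for p in cfg.region_sets]
    cfg.baf_table = _resolve(cfg.baf_table)
    cfg.genome_fasta = _resolve(cfg.genome_fasta)
    for s in cfg.samples:
        s.bam = _resolve(s.bam)
        s.bed = _resolve(s.bed)
        s.gdna_bam = _resolve(s.gdna_bam)
    cfg.validate_paths()
    return cfg
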