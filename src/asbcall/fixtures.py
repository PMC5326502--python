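"""Self-consistent micro-datasets for end-to-end testing.

Builds a kilobase-scale random genome, plants heterozygous SNPs with known
allelic balance eta and background reference-allele frequency rho, writes
reads over each SNP to per-sample indexed BAM files, and emits the matching
peak BED, SNP TSV, BAF TSV, and a truth table.  Everything is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .io import write_bed, write_fasta, write_snp_table
from .simulate import simulate_counts
from .types import HetSNP, RegionSet

__all__ = ["FixturePaths", "make_fixture", "make_toy_genome"]

_QUAL = 40  # uniform base quality of fixture reads
_BASES = "ACGT"


@dataclass(frozen=True)
class FixturePaths:
    """File locations of one generated micro-dataset."""

    genome_fasta: Path
    snp_table: Path
    baf_table: Path
    peaks_bed: Path
    bam_paths: dict[str, Path]
    truth_table: Path
    out_dir: Path


def make_toy_genome(rng: np.random.Generator, length: int, chrom: str = "chr1") -> dict[str, str]:
    seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    return {chrom: seq}


def _read_for(
    genome_seq: str, pos0: int, allele: str, offset: int, read_length: int
) -> tuple[int, str]:
    start = pos0 - offset
    window = genome_seq[start : start + read_length]
    return start, window[:offset] + allele + window[offset + 1 :]


def make_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_snps: int = 4,
    read_length: int = 36,
    depth: int = 100,
    allelic_ratios: Sequence[float] | None = None,
    raf_values: Sequence[float] | None = None,
    n_replicates: int = 2,
    experiment: str = "TF1",
    spacing: int = 400,
) -> FixturePaths:
    """Write a complete micro-dataset with known per-SNP truth.

    allelic_ratios (eta) and raf_values (rho) default to 0.5 everywhere;
    counts per sample follow the two-stage binomial hierarchy used by the
    in-silico validation, so the planted eta is recoverable by the model.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    etas = list(allelic_ratios) if allelic_ratios is not None else [0.5] * n_snps
    rhos = list(raf_values) if raf_values is not None else [0.5] * n_snps
    if len(etas) != n_snps or len(rhos) != n_snps:
        raise ValueError("allelic_ratios and raf_values must have length n_snps")

    rng = np.random.default_rng(seed)
    margin = 2 * read_length
    chrom = "chr1"
    genome = make_toy_genome(rng, 2 * margin + n_snps * spacing, chrom)
    seq = genome[chrom]

    snps: list[HetSNP] = []
    for i in range(n_snps):
        pos0 = margin + i * spacing
        ref = seq[pos0]
        alt = rng.permutation([b for b in _BASES if b != ref])[0]
        snps.append(HetSNP(id=f"snp{i + 1}", chrom=chrom, pos=pos0 + 1, ref=ref, alt=str(alt)))

    peaks = RegionSet("peaks")
    for snp in snps:
        peaks.add(chrom, snp.pos0 - read_length, snp.pos0 + read_length)

    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": len(seq)}]}
    bam_paths: dict[str, Path] = {}
    for rep in range(1, n_replicates + 1):
        sample_id = f"{experiment}_rep{rep}"
        reads: list[tuple[int, str, str]] = []  # (start, name, seq)
        for snp, eta, rho in zip(snps, etas, rhos):
            (a, d), = simulate_counts(1, depth, rho, eta, rng)
            alleles = [snp.ref] * a + [snp.alt] * (d - a)
            offsets = rng.integers(0, read_length, size=d)
            for j, (allele, off) in enumerate(zip(alleles, offsets)):
                start, rseq = _read_for(seq, snp.pos0, allele, int(off), read_length)
                reads.append((start, f"{snp.id}_{sample_id}_r{j}", rseq))
        reads.sort()
        bam_path = out / f"{sample_id}.bam"
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
            for start, name, rseq in reads:
                rec = pysam.AlignedSegment(bam.header)
                rec.query_name = name
                rec.query_sequence = rseq
                rec.flag = 0
                rec.reference_id = 0
                rec.reference_start = start
                rec.mapping_quality = 60
                rec.cigarstring = f"{len(rseq)}M"
                rec.query_qualities = pysam.qualitystring_to_array(chr(_QUAL + 33) * len(rseq))
                bam.write(rec)
        pysam.index(str(bam_path))
        bam_paths[sample_id] = bam_path

    genome_fasta = out / "genome.fa"
    write_fasta(genome, genome_fasta)
    snp_table = out / "snps.tsv"
    write_snp_table(snps, snp_table)
    peaks_bed = out / "peaks.bed"
    write_bed(peaks, peaks_bed)

    # BAF table with the array's B allele set to the alternative allele,
    # so RAF = 1 - BAF exercises the conversion path
    baf_table = out / "baf.tsv"
    pd.DataFrame(
        {
            "ID": [s.id for s in snps],
            "BAF": [1.0 - rho for rho in rhos],
            "ALLELE_A": [s.ref for s in snps],
            "ALLELE_B": [s.alt for s in snps],
        }
    ).to_csv(baf_table, sep="\t", index=False)

    config = {
        "snp_table": "snps.tsv",
        "baf_table": "baf.tsv",
        "genome_fasta": "genome.fa",
        "read_length": read_length,
        "output_dir": str(out / "asbcall_out"),
        "samples": [
            {
                "sample_id": sid,
                "experiment": experiment,
                "replicate": sid.rsplit("_", 1)[-1],
                "bam": f"{sid}.bam",
                "bed": "peaks.bed",
            }
            for sid in bam_paths
        ],
    }
    import yaml

    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    truth_table = out / "truth.tsv"
    pd.DataFrame(
        {
            "ID": [s.id for s in snps],
            "eta": etas,
            "rho": rhos,
            "depth": depth,
            "n_replicates": n_replicates,
        }
    ).to_csv(truth_table, sep="\t", index=False)

    return FixturePaths(
        genome_fasta=genome_fasta,
        snp_table=snp_table,
        baf_table=baf_table,
        peaks_bed=peaks_bed,
        bam_paths=bam_paths,
        truth_table=truth_table,
        out_dir=out,
    )
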