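"""Allelic read counting at heterozygous SNPs inside peak regions.

Counts are strictly biallelic: at each SNP only bases equal to the ref or
alt allele contribute (a and d = a + alt); other bases are tallied in a side
log, since they almost always reflect sequencing error.  Reads must exceed
the mapping-quality threshold and the base at the SNP must exceed the
base-quality threshold.  Duplicate-flagged, secondary, supplementary and
QC-fail alignments are skipped, and overlapping mates of a pair are counted
once per fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pysam

from .types import AlleleCountTable, HetSNP, RegionSet

logger = logging.getLogger(__name__)

__all__ = ["SampleAlignments", "pileup_sample", "pileup_counts"]


@dataclass(frozen=True)
class SampleAlignments:
    """One sample's alignment file plus its peak set."""

    sample_id: str
    bam_path: str
    peaks: RegionSet | None = None


def _count_at_snp(
    bam: pysam.AlignmentFile,
    snp: HetSNP,
    min_mapq: int,
    min_baseq: int,
) -> tuple[int, int, int]:
    """(ref, alt, other) base counts at one SNP, one fragment per pair."""
    if snp.chrom not in bam.references:
        raise ValueError(
            f"chromosome {snp.chrom!r} of SNP {snp.id} not present in alignment file "
            f"{bam.filename!r} (references: {list(bam.references)[:5]}...)"
        )
    n_ref = n_alt = n_other = 0
    seen_fragments: set[str] = set()
    for read in bam.fetch(snp.chrom, snp.pos0, snp.pos0 + 1):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_duplicate or read.is_qcfail:
            continue
        if read.mapping_quality <= min_mapq:
            continue
        qpos = None
        for q, r in read.get_aligned_pairs(matches_only=True):
            if r == snp.pos0:
                qpos = q
                break
        if qpos is None:
            continue
        if read.query_qualities is not None and read.query_qualities[qpos] <= min_baseq:
            continue
        if read.query_name in seen_fragments:  # overlapping mate: one count per fragment
            continue
        seen_fragments.add(read.query_name)
        base = read.query_sequence[qpos].upper()
        if base == snp.ref:
            n_ref += 1
        elif base == snp.alt:
            n_alt += 1
        else:
            n_other += 1
    return n_ref, n_alt, n_other


def pileup_sample(
    bam_path: str,
    snps: Sequence[HetSNP],
    peaks: RegionSet | None,
    min_mapq: int = 15,
    min_baseq: int = 10,
) -> dict[str, tuple[int, int, bool]]:
    """Per-SNP (a, d, in_peak) for one sample; SNPs outside peaks get (0, 0, False).

    Requires a coordinate-sorted, indexed BAM.  Bases matching neither allele
    are excluded from a and d and logged.
    """
    out: dict[str, tuple[int, int, bool]] = {}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"alignment file {bam_path} has no index; run samtools index first")
        n_other_total = 0
        for snp in snps:
            in_peak = peaks is None or peaks.contains(snp.chrom, snp.pos0)
            if not in_peak:
                out[snp.id] = (0, 0, False)
                continue
            n_ref, n_alt, n_other = _count_at_snp(bam, snp, min_mapq, min_baseq)
            n_other_total += n_other
            out[snp.id] = (n_ref, n_ref + n_alt, True)
    if n_other_total:
        logger.info("%s: %d bases matched neither allele and were excluded", bam_path, n_other_total)
    return out


def pileup_counts(
    samples: Sequence[SampleAlignments],
    snps: Sequence[HetSNP],
    replicate_groups: Mapping[str, Sequence[str]] | None = None,
    min_mapq: int = 15,
    min_baseq: int = 10,
) -> AlleleCountTable:
    """Build the SNP x sample allele-count table from per-sample alignments.

    A cell is MISSING when the SNP lies outside that sample's peaks; a SNP in
    a peak but with zero coverage gets (a=0, d=0) and is left for the
    downstream replicate-consistency filter to judge.
    """
    table = AlleleCountTable.empty(
        [s.id for s in snps], [s.sample_id for s in samples], replicate_groups
    )
    for sample in samples:
        per_snp = pileup_sample(sample.bam_path, snps, sample.peaks, min_mapq, min_baseq)
        for snp in snps:
            a, d, in_peak = per_snp[snp.id]
            if in_peak:
                table.set_cell(snp.id, sample.sample_id, a, d, True)
    return table
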