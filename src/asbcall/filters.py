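"""QC filters on heterozygous SNPs and the allele-count table.

Order used by the pipeline (per-site filters first, then replicate-level):
problematic-region exclusion, simulated-read intrinsic-bias exclusion,
replicate-consistency masking, and finally removal of SNPs where only one
allele was ever observed (possible undetected homozygotes).
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .types import AlleleCountTable, HetSNP, RegionSet

__all__ = [
    "RemovalLog",
    "filter_regions",
    "SimulatedRead",
    "generate_simulated_reads",
    "ExactMatchAligner",
    "CommandLineAligner",
    "intrinsic_bias_filter",
    "replicate_consistency_filter",
    "unique_allele_filter",
    "merge_replicate_peaks",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RemovalLog:
    """Per-filter record of removed SNPs: (snp_id, reason)."""

    filter_name: str
    removed: list[tuple[str, str]]

    @property
    def removed_ids(self) -> set[str]:
        return {snp_id for snp_id, _ in self.removed}

    def __len__(self) -> int:
        return len(self.removed)


def filter_regions(
    snps: Sequence[HetSNP], region_sets: Sequence[RegionSet]
) -> tuple[list[HetSNP], RemovalLog]:
    """Drop SNPs intersecting any interval of any region set (blacklists etc.).

    Empty region-set list is a no-op. The log records which set triggered
    each removal (first matching set).
    """
    kept: list[HetSNP] = []
    removed: list[tuple[str, str]] = []
    for snp in snps:
        hit = next((rs.name for rs in region_sets if rs.contains(snp.chrom, snp.pos0)), None)
        if hit is None:
            kept.append(snp)
        else:
            removed.append((snp.id, hit))
    return kept, RemovalLog("problematic_regions", removed)


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read overlapping a het SNP."""

    name: str
    sequence: str
    chrom: str
    start: int  # expected 0-based alignment start on the plus strand
    strand: str  # '+' or '-'
    allele: str  # 'ref' or 'alt'


def generate_simulated_reads(
    snp: HetSNP, genome: Mapping[str, str], read_length: int
) -> list[SimulatedRead]:
    """Every possible read overlapping the SNP, for both alleles and strands.

    For each of the read_length alignment offsets covering the SNP, emits the
    ref-carrying and alt-carrying sequence on plus and minus strands:
    4 * read_length reads, 2 * read_length per allele.  Base qualities are
    uniform (maximum) and depth is not varied.
    """
    seq = genome[snp.chrom]
    if snp.pos0 - (read_length - 1) < 0 or snp.pos0 + read_length > len(seq):
        raise ValueError(
            f"SNP {snp.id} at {snp.chrom}:{snp.pos} is within {read_length - 1} bp of a sequence end"
        )
    reads: list[SimulatedRead] = []
    for offset in range(read_length):
        start = snp.pos0 - offset
        window = seq[start : start + read_length].upper()
        for allele_name, base in (("ref", snp.ref), ("alt", snp.alt)):
            fwd = window[:offset] + base + window[offset + 1 :]
            for strand, s in (("+", fwd), ("-", revcomp(fwd))):
                reads.append(
                    SimulatedRead(
                        name=f"{snp.id}_{allele_name}_{offset}_{strand}",
                        sequence=s,
                        chrom=snp.chrom,
                        start=start,
                        strand=strand,
                        allele=allele_name,
                    )
                )
    return reads


class Aligner(Protocol):
    """Adapter mapping read sequences to genome loci."""

    def align(self, reads: Sequence[SimulatedRead], genome: Mapping[str, str]) -> dict[str, tuple[str, int] | None]:
        """For each read name: its unique (chrom, start) locus, or None if
        unmapped/multi-mapping."""
        ...


class ExactMatchAligner:
    """Built-in aligner for the intrinsic-bias filter: near-exact full scan.

    A read is reported as aligned only if its sequence (on either strand)
    occurs at exactly one genome locus allowing at most ``max_mismatches``
    mismatches — enough slack for the single allele substitution at the SNP.
    """

    def __init__(self, max_mismatches: int = 1) -> None:
        self.max_mismatches = max_mismatches

    @staticmethod
    def _encode(seq: str) -> np.ndarray:
        return np.frombuffer(seq.upper().encode(), dtype=np.uint8)

    def _loci(self, read_seq: str, chrom_arrays: Mapping[str, np.ndarray]) -> list[tuple[str, int]]:
        loci: list[tuple[str, int]] = []
        L = len(read_seq)
        queries = [self._encode(read_seq), self._encode(revcomp(read_seq))]
        for chrom, arr in chrom_arrays.items():
            if arr.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            for q in queries:
                mism = (windows != q).sum(axis=1)
                for start in np.flatnonzero(mism <= self.max_mismatches):
                    loci.append((chrom, int(start)))
        return sorted(set(loci))

    def align(
        self, reads: Sequence[SimulatedRead], genome: Mapping[str, str]
    ) -> dict[str, tuple[str, int] | None]:
        chrom_arrays = {c: self._encode(genome[c]) for c in genome}
        out: dict[str, tuple[str, int] | None] = {}
        cache: dict[str, list[tuple[str, int]]] = {}
        for read in reads:
            key = min(read.sequence, revcomp(read.sequence))
            if key not in cache:
                cache[key] = self._loci(read.sequence, chrom_arrays)
            loci = cache[key]
            out[read.name] = loci[0] if len(loci) == 1 else None
        return out


class CommandLineAligner:
    """Process-call adapter for an external short-read aligner.

    ``command`` is a template with {fasta}, {genome} and {sam} placeholders;
    it must write SAM output mapping read names to loci, e.g.::

        bwa index {genome} && bwa mem {genome} {fasta} > {sam}

    Reads with mapping quality below ``min_mapq`` or unmapped are reported
    as None.
    """

    def __init__(self, command: str, min_mapq: int = 1) -> None:
        self.command = command
        self.min_mapq = min_mapq

    def align(
        self, reads: Sequence[SimulatedRead], genome: Mapping[str, str]
    ) -> dict[str, tuple[str, int] | None]:
        import pysam

        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp)
            fasta = tmp_path / "reads.fa"
            genome_fa = tmp_path / "genome.fa"
            sam = tmp_path / "out.sam"
            fasta.write_text("".join(f">{r.name}\n{r.sequence}\n" for r in reads))
            genome_fa.write_text("".join(f">{c}\n{genome[c]}\n" for c in genome))
            cmd = self.command.format(fasta=fasta, genome=genome_fa, sam=sam)
            try:
                subprocess.run(cmd, shell=True, check=True, capture_output=True)
            except subprocess.CalledProcessError as exc:  # pragma: no cover
                raise RuntimeError(f"external aligner failed: {exc.stderr.decode()[:500]}") from exc
            out: dict[str, tuple[str, int] | None] = {r.name: None for r in reads}
            with pysam.AlignmentFile(str(sam), "r") as af:
                for rec in af:
                    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                        continue
                    if rec.mapping_quality < self.min_mapq:
                        out[rec.query_name] = None
                    else:
                        out[rec.query_name] = (rec.reference_name, rec.reference_start)
        return out


def intrinsic_bias_filter(
    snps: Sequence[HetSNP],
    genome: Mapping[str, str],
    aligner: Aligner | None = None,
    read_length: int = 36,
) -> tuple[list[HetSNP], RemovalLog]:
    """Drop SNPs whose simulated reads do not all realign uniquely and correctly.

    For each SNP, every simulated read of each allele must map back to the
    SNP's own locus; a SNP is kept only if exactly 2 * read_length reads per
    allele do so.  Any shortfall signals an intrinsic mapping bias toward one
    allele (homology elsewhere in the genome, repeats, ...).
    """
    aligner = aligner or ExactMatchAligner()
    kept: list[HetSNP] = []
    removed: list[tuple[str, str]] = []
    expected = 2 * read_length
    for snp in snps:
        try:
            reads = generate_simulated_reads(snp, genome, read_length)
        except ValueError as exc:
            removed.append((snp.id, f"unsimulatable: {exc}"))
            continue
        aligned = aligner.align(reads, genome)
        correct = {"ref": 0, "alt": 0}
        for read in reads:
            locus = aligned.get(read.name)
            if locus == (read.chrom, read.start):
                correct[read.allele] += 1
        if correct["ref"] == expected and correct["alt"] == expected:
            kept.append(snp)
        else:
            removed.append(
                (snp.id, f"ref {correct['ref']}/{expected}, alt {correct['alt']}/{expected}")
            )
    return kept, RemovalLog("intrinsic_bias", removed)


def replicate_consistency_filter(table: AlleleCountTable) -> tuple[AlleleCountTable, RemovalLog]:
    """Mask SNPs not represented (with coverage) in all replicates of an experiment.

    Within each replicate group, a SNP is kept only if every replicate has a
    non-missing cell with nonzero total count; otherwise the SNP is masked
    for that whole experiment.  With no replicate groups, or single-replicate
    groups where the sole cell is covered, this is the identity.
    """
    out = table.copy()
    masked: list[tuple[str, str]] = []
    groups = table.replicate_groups or {s: [s] for s in table.sample_ids}
    for snp_id in table.snp_ids:
        for exp, samples in groups.items():
            covered = [
                not table.is_missing(snp_id, s) and table.total.at[snp_id, s] > 0
                for s in samples
            ]
            if not all(covered):
                if any(covered):  # only log when the mask removes information
                    masked.append((snp_id, exp))
                out.set_missing(snp_id, samples)
    return out, RemovalLog("replicate_consistency", masked)


def unique_allele_filter(table: AlleleCountTable) -> tuple[AlleleCountTable, RemovalLog]:
    """Drop SNPs where only one allele was observed after pooling all samples.

    Pooled ref count of 0 or pooled alt count of 0 marks a possible
    undetected homozygote.  SNPs with no data at all are also dropped here.
    """
    kept_ids: list[str] = []
    removed: list[tuple[str, str]] = []
    for snp_id in table.snp_ids:
        a, d = table.pooled(snp_id)
        if d == 0:
            removed.append((snp_id, "no data"))
        elif a == 0:
            removed.append((snp_id, "reference allele never observed"))
        elif a == d:
            removed.append((snp_id, "alternative allele never observed"))
        else:
            kept_ids.append(snp_id)
    return table.subset(kept_ids), RemovalLog("unique_allele", removed)


def merge_replicate_peaks(peak_sets: Iterable[RegionSet], name: str = "merged") -> RegionSet:
    """Intersection of peak sets across replicates: keep only positions called
    in every replicate (interval intersection, computed per chromosome)."""
    sets = list(peak_sets)
    if not sets:
        return RegionSet(name)
    merged = RegionSet(name)
    chroms = set(sets[0].chroms())
    for rs in sets[1:]:
        chroms &= set(rs.chroms())
    for chrom in sorted(chroms):
        pieces = [rs.intervals(chrom) for rs in sets]
        current = pieces[0]
        for other in pieces[1:]:
            nxt: list[tuple[int, int]] = []
            for s1, e1 in current:
                for s2, e2 in other:
                    s, e = max(s1, s2), min(e1, e2)
                    if s < e:
                        nxt.append((s, e))
            current = nxt
        for s, e in current:
            merged.add(chrom, s, e)
    return merged
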