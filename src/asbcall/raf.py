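"""Reference-allele frequency (RAF, rho) per SNP.

rho is the background genomic fraction of the reference allele: 0.5 in a
balanced diploid region, skewed toward 0 or 1 under copy-number alteration
or loss of heterozygosity.  It can be obtained by converting SNP-array
B-allele-frequency (BAF) scores, or directly as a/d from genomic-DNA
(input) read counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "BAFRecord",
    "raf_from_baf",
    "baf_homozygous_filter",
    "raf_from_gdna",
    "assign_raf",
]


@dataclass(frozen=True)
class BAFRecord:
    """SNP-array record: B-allele frequency plus the array's A/B allele bases."""

    snp_id: str
    baf: float | None
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: array alleles A and B are identical")
        if self.baf is not None and not 0.0 <= self.baf <= 1.0:
            raise ValueError(f"{self.snp_id}: BAF must be in [0,1], got {self.baf}")


def raf_from_baf(rec: BAFRecord, ref: str) -> float:
    """Convert BAF to RAF: BAF if the reference allele is the array's B allele,
    1 - BAF if it is the A allele."""
    if rec.baf is None:
        raise ValueError(f"{rec.snp_id}: missing BAF score")
    if ref == rec.allele_b:
        return rec.baf
    if ref == rec.allele_a:
        return 1.0 - rec.baf
    raise ValueError(
        f"{rec.snp_id}: reference allele {ref} matches neither array allele "
        f"(A={rec.allele_a}, B={rec.allele_b})"
    )


def baf_homozygous_filter(records: Iterable[BAFRecord]) -> list[BAFRecord]:
    """Drop likely-homozygous records: BAF > 0.9 or < 0.1, or missing BAF."""
    return [r for r in records if r.baf is not None and 0.1 <= r.baf <= 0.9]


def raf_from_gdna(a: int, d: int, min_cov: int = 10) -> float | None:
    """RAF from genomic-DNA allelic counts: a/d, or None (unusable) below min_cov.

    min_cov=10 keeps the binomial standard error on rho below about 0.16.
    """
    if d < min_cov:
        return None
    return a / d


def assign_raf(
    snps: Sequence,
    baf_records: dict[str, BAFRecord] | None = None,
    gdna_counts: dict[str, tuple[int, int]] | None = None,
    min_cov: int = 10,
) -> list[str]:
    """Populate snp.raf in place; returns ids left without a usable RAF.

    Precedence per SNP: an already-present raf (user-supplied column) wins;
    then gDNA counts (more direct); then BAF conversion.
    """
    unassigned: list[str] = []
    for snp in snps:
        if snp.raf is not None:
            continue
        if gdna_counts and snp.id in gdna_counts:
            a, d = gdna_counts[snp.id]
            rho = raf_from_gdna(a, d, min_cov)
            if rho is not None:
                snp.raf = rho
                continue
        if baf_records and snp.id in baf_records:
            rec = baf_records[snp.id]
            if rec.baf is not None:
                snp.raf = raf_from_baf(rec, snp.ref)
                continue
        unassigned.append(snp.id)
    return unassigned
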