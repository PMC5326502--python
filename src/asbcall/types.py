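"""Core data containers: heterozygous SNPs, region sets, and the allele-count table."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["HetSNP", "RegionSet", "AlleleCountTable"]

_BASES = {"A", "C", "G", "T"}


@dataclass
class HetSNP:
    """One heterozygous variant.

    pos is 1-based (SNP-table convention); internal interval logic converts
    to 0-based half-open at the point of use.  raf (reference-allele
    frequency, rho) and rm_bias (reference-mapping bias, mu) are annotated by
    the raf and qc modules respectively.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    raf: float | None = None
    rm_bias: float | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"SNP {self.id}: alleles must be A/C/G/T, got ref={self.ref} alt={self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"SNP {self.id}: ref and alt alleles are identical ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: 1-based position must be >= 1, got {self.pos}")
        if self.raf is not None and not 0.0 <= self.raf <= 1.0:
            raise ValueError(f"SNP {self.id}: RAF must be in [0,1], got {self.raf}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1

    @property
    def category(self) -> str:
        """Ordered allele-pair category for reference-mapping-bias pooling."""
        return f"{self.ref}>{self.alt}"


class RegionSet:
    """A named set of genomic intervals (0-based, half-open), e.g. a blacklist."""

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"region {chrom}:{start}-{end}: start must be < end (0-based half-open)")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chrom: str, pos0: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos0, pos0 + 1))

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree)

    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionSet({self.name!r}, {len(self)} intervals)"


class AlleleCountTable:
    """SNP x sample matrix of allelic counts with explicit missingness.

    Three aligned DataFrames indexed by SNP id with one column per sample:
    ref counts (a), total biallelic counts (d = a + alt), and a boolean
    in-peak flag.  A cell is MISSING (NaN) when the SNP lies outside that
    sample's peaks or failed QC for that sample.  replicate_groups maps an
    experiment name to its replicate sample ids.
    """

    def __init__(
        self,
        ref: pd.DataFrame,
        total: pd.DataFrame,
        peak: pd.DataFrame | None = None,
        replicate_groups: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        if not ref.index.equals(total.index) or list(ref.columns) != list(total.columns):
            raise ValueError("ref and total count frames must share index and columns")
        with np.errstate(invalid="ignore"):
            bad = (ref > total).to_numpy()
        if np.nansum(bad):
            raise ValueError("ref count exceeds total count in some cell")
        self.ref = ref.astype(float)
        self.total = total.astype(float)
        self.peak = (
            peak.astype(bool)
            if peak is not None
            else total.notna()
        )
        self.replicate_groups = {k: list(v) for k, v in (replicate_groups or {}).items()}

    # -- construction ------------------------------------------------------
    @classmethod
    def empty(
        cls,
        snp_ids: Sequence[str],
        sample_ids: Sequence[str],
        replicate_groups: Mapping[str, Sequence[str]] | None = None,
    ) -> "AlleleCountTable":
        shape = (len(snp_ids), len(sample_ids))
        nan = pd.DataFrame(np.full(shape, np.nan), index=list(snp_ids), columns=list(sample_ids))
        return cls(nan.copy(), nan.copy(), nan.notna(), replicate_groups)

    # -- accessors ---------------------------------------------------------
    @property
    def snp_ids(self) -> list[str]:
        return list(self.ref.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ref.columns)

    def is_missing(self, snp_id: str, sample_id: str) -> bool:
        return bool(pd.isna(self.total.at[snp_id, sample_id]))

    def set_cell(self, snp_id: str, sample_id: str, a: int, d: int, in_peak: bool = True) -> None:
        if a > d:
            raise ValueError(f"a={a} > d={d} at {snp_id}/{sample_id}")
        self.ref.at[snp_id, sample_id] = a
        self.total.at[snp_id, sample_id] = d
        self.peak.at[snp_id, sample_id] = in_peak

    def set_missing(self, snp_id: str, sample_ids: Sequence[str] | None = None) -> None:
        cols = list(sample_ids) if sample_ids is not None else self.sample_ids
        self.ref.loc[snp_id, cols] = np.nan
        self.total.loc[snp_id, cols] = np.nan
        self.peak.loc[snp_id, cols] = False

    def pooled(self, snp_id: str) -> tuple[int, int]:
        """(pooled ref, pooled total) over non-missing cells of one SNP."""
        a = self.ref.loc[snp_id]
        d = self.total.loc[snp_id]
        return int(np.nansum(a)), int(np.nansum(d))

    def counts_for(self, snp_id: str) -> list[tuple[int, int]]:
        """Non-missing (a, d) pairs for one SNP, in sample order."""
        out = []
        for s in self.sample_ids:
            d = self.total.at[snp_id, s]
            if not pd.isna(d):
                out.append((int(self.ref.at[snp_id, s]), int(d)))
        return out

    def subset(self, snp_ids: Sequence[str]) -> "AlleleCountTable":
        ids = list(snp_ids)
        return AlleleCountTable(
            self.ref.loc[ids].copy(),
            self.total.loc[ids].copy(),
            self.peak.loc[ids].copy(),
            self.replicate_groups,
        )

    def copy(self) -> "AlleleCountTable":
        return self.subset(self.snp_ids)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AlleleCountTable({len(self.snp_ids)} SNPs x {len(self.sample_ids)} samples)"
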