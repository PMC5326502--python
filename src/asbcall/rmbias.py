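"""Reference-mapping-bias estimation from QC-passing allelic counts.

Short-read aligners favor reads matching the reference genome, so even a
perfectly balanced het SNP shows a reference-allele read fraction slightly
above 0.5.  The expected allelic ratio mu is estimated empirically by
pooling reads across all QC-passing sites, separately for each ordered
ref>alt allele pair (12 categories); sparse categories fall back to the
global pooled estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .types import AlleleCountTable, HetSNP

__all__ = ["RMBiasTable", "estimate_rm_bias", "ALLELE_CATEGORIES"]

ALLELE_CATEGORIES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)  # 12 ordered ref>alt pairs


@dataclass
class RMBiasTable:
    """Per-category expected reference ratio mu with a global fallback.

    categories maps "R>A" to (mu_cat, n_sites); categories with fewer than
    min_sites SNPs are assigned mu_global instead.
    """

    categories: dict[str, tuple[float, int]]
    mu_global: float
    min_sites: int = 200

    def mu_for(self, ref: str, alt: str) -> float:
        cat = self.categories.get(f"{ref}>{alt}")
        if cat is None or cat[1] < self.min_sites:
            return self.mu_global
        return cat[0]


def estimate_rm_bias(
    table: AlleleCountTable, snps: Sequence[HetSNP], min_sites: int = 200
) -> RMBiasTable:
    """Pooled reference ratio per allele-pair category, annotated onto the SNPs.

    mu_cat = sum(a) / sum(d) over all category SNPs present in the (already
    QC-filtered) count table, reads pooled across samples; the global
    estimate pools everything.  Each SNP's ``rm_bias`` field is set to its
    category's mu.  Raises if no SNP has any data.
    """
    by_id = {s.id: s for s in snps}
    sums: dict[str, list[int]] = {}
    tot_a = tot_d = 0
    n_sites: dict[str, int] = {}
    for snp_id in table.snp_ids:
        snp = by_id.get(snp_id)
        if snp is None:
            continue
        a, d = table.pooled(snp_id)
        if d == 0:
            continue
        acc = sums.setdefault(snp.category, [0, 0])
        acc[0] += a
        acc[1] += d
        n_sites[snp.category] = n_sites.get(snp.category, 0) + 1
        tot_a += a
        tot_d += d
    if tot_d == 0:
        raise ValueError("no QC-passing SNPs with read data; cannot estimate reference mapping bias")
    categories = {
        cat: (acc[0] / acc[1], n_sites[cat]) for cat, acc in sums.items() if acc[1] > 0
    }
    result = RMBiasTable(categories, tot_a / tot_d, min_sites)
    for snp_id in table.snp_ids:
        snp = by_id.get(snp_id)
        if snp is not None:
            snp.rm_bias = result.mu_for(snp.ref, snp.alt)
    return result
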