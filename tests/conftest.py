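from __future__ import annotations

import numpy as np
import pysam
import pytest
from hypothesis import settings

from asbcall.model import ModelHyperParams, SNPModelInput, log_posterior_eta

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def grid_posterior_summary(
    snp: SNPModelInput, hp: ModelHyperParams = ModelHyperParams(), n: int = 2001
) -> tuple[float, float]:
    """Independent oracle: posterior mean/variance by grid normalization.

    Evaluates the unnormalized log posterior on an n-point eta grid strictly
    inside (0,1) and integrates with the trapezoid rule.
    """
    eta = np.linspace(0.0, 1.0, n + 2)[1:-1]
    lp = log_posterior_eta(eta, snp, hp)
    w = np.exp(lp - lp.max())
    z = np.trapezoid(w, eta)
    mean = np.trapezoid(w * eta, eta) / z
    var = np.trapezoid(w * (eta - mean) ** 2, eta) / z
    return float(mean), float(var)


def brute_force_hpd(trace, mass: float) -> tuple[float, float]:
    """Exhaustive minimal-width window over the sorted trace."""
    import math

    x = np.sort(np.asarray(trace, dtype=float))
    n = x.size
    m = math.ceil(mass * n)
    best = None
    for i in range(n - m + 1):
        lo, hi = x[i], x[i + m - 1]
        if best is None or hi - lo < best[1] - best[0]:
            best = (lo, hi)
    return float(best[0]), float(best[1])


@pytest.fixture
def bam_factory(tmp_path):
    """Write a coordinate-sorted, indexed BAM on chr1 (length 1000) from read specs.

    Each spec: dict(name, start, seq, mapq=30, baseq=30, flag=0,
    baseq_list=None).
    """

    def _make(reads, filename="sample.bam", chrom="chr1", length=1000):
        header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
        path = tmp_path / filename
        reads = sorted(reads, key=lambda r: r["start"])
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for spec in reads:
                rec = pysam.AlignedSegment(bam.header)
                rec.query_name = spec["name"]
                rec.query_sequence = spec["seq"]
                rec.flag = spec.get("flag", 0)
                rec.reference_id = 0
                rec.reference_start = spec["start"]
                rec.mapping_quality = spec.get("mapq", 30)
                rec.cigarstring = f"{len(spec['seq'])}M"
                quals = spec.get("baseq_list") or [spec.get("baseq", 30)] * len(spec["seq"])
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                bam.write(rec)
        pysam.index(str(path))
        return str(path)

    return _make
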