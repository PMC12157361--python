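"""Genome-instability metrics: WGD, wGII, telomere ratio, mitochondrial CN.

All interval-based rules are length-weighted, which makes every metric
invariant to how finely the segmentation happens to subdivide a region.
"""

from __future__ import annotations

import math

from .types import CNSegment, ReadGroupTelomere, SamplePloidyModel

__all__ = [
    "call_wgd",
    "compute_wgii",
    "count_telomeric_reads",
    "estimate_sample_tl",
    "tl_log2_ratio",
    "mito_copy_number",
    "AUTOSOMES",
]

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

WGD_MAJOR_CN_MIN = 3  # whole-genome doubling when major CN >= 3 ...
WGD_FRAC_MIN = 0.5  # ... on more than half the genome

TELOMERE_REPEATS = ("TTAGGG", "CCCTAA")
TELOMERE_REPEAT_MIN = 7


def call_wgd(
    segments: list[CNSegment],
    major_cn_min: int = WGD_MAJOR_CN_MIN,
    frac_min: float = WGD_FRAC_MIN,
    length_weighted: bool = True,
) -> bool:
    """Whole-genome doubling: major CN >= cutoff on more than half the genome.

    The fraction is length-weighted by default (robust to segmentation
    granularity); ``length_weighted=False`` counts segments instead.
    The inequality against ``frac_min`` is strict ("more than 50%").
    """
    if not segments:
        raise ValueError("cannot call WGD on an empty segment list")
    if length_weighted:
        total = sum(s.length for s in segments)
        high = sum(s.length for s in segments if s.major_cn >= major_cn_min)
    else:
        total = len(segments)
        high = sum(1 for s in segments if s.major_cn >= major_cn_min)
    return high / total > frac_min


def compute_wgii(
    segments: list[CNSegment],
    autosomes: tuple[str, ...] = AUTOSOMES,
) -> float:
    """Weighted genome instability index.

    The length-weighted mean TCN over all segments defines the sample
    ploidy; per autosome, the aberrant fraction is the length fraction
    whose rounded TCN differs from the rounded ploidy; the 22 per-
    autosome fractions are summed and divided by 22 (autosomes without
    segments contribute 0).
    """
    segs = [s for s in segments if s.tcn is not None]
    if not segs:
        raise ValueError("wGII needs segments with corrected TCN annotation")
    total = sum(s.length for s in segs)
    ploidy_lw = sum(s.length * s.tcn for s in segs) / total
    ref = round(ploidy_lw)
    acc = 0.0
    for chrom in autosomes:
        chrom_segs = [s for s in segs if s.chrom == chrom]
        if not chrom_segs:
            continue
        clen = sum(s.length for s in chrom_segs)
        aberrant = sum(s.length for s in chrom_segs if round(s.tcn) != ref)
        acc += aberrant / clen
    return acc / len(autosomes)


def count_telomeric_reads(reads) -> int:
    """Count reads with >= 7 non-overlapping TTAGGG or CCCTAA repeats."""
    n = 0
    for read in reads:
        seq = read.upper()
        if any(seq.count(rep) >= TELOMERE_REPEAT_MIN for rep in TELOMERE_REPEATS):
            n += 1
    return n


def estimate_sample_tl(groups: list[ReadGroupTelomere], c: float = 1.0) -> float:
    """Read-count-weighted mean of per-read-group telomere lengths.

    Each group's TL is ``c * n_telomeric / n_reads``; the scale constant
    ``c`` defaults to 1 (arbitrary units) and cancels in the downstream
    tumor/normal log ratio.
    """
    total_reads = sum(g.n_reads for g in groups)
    if total_reads == 0:
        raise ValueError("zero total reads across read groups")
    return sum(g.n_reads * g.tl_kb(c) for g in groups) / total_reads


def tl_log2_ratio(tumor_tl: float, normal_tl: float) -> float:
    """log2 telomere-length ratio between tumor and matched normal."""
    if tumor_tl <= 0 or normal_tl <= 0:
        raise ValueError("telomere lengths must be positive")
    return math.log2(tumor_tl / normal_tl)


def mito_copy_number(
    depth_mt_t: float,
    depth_nuc_t: float,
    depth_mt_n: float,
    depth_nuc_n: float,
    model: SamplePloidyModel,
) -> float:
    """Purity/ploidy-adjusted tumor-cell mitochondrial copy number.

    The tumor sample's mito/nuclear depth ratio reflects a mixture of
    tumor cells (nuclear content psi) and normal cells (nuclear content
    2). Scaling the ratio by the mixture nuclear content
    ``Pe = rho * psi + 2 * (1 - rho)`` gives mitochondrial copies per
    mixture cell, from which the normal-cell contribution (estimated
    from the matched normal) is subtracted before dividing by purity.
    """
    if min(depth_mt_t, depth_nuc_t, depth_mt_n, depth_nuc_n) <= 0:
        raise ValueError("read depths must be positive")
    rho, psi = model.purity, model.ploidy
    r_t = depth_mt_t / depth_nuc_t
    pe = rho * psi + 2.0 * (1.0 - rho)
    mixture_mt = r_t * pe
    normal_mt = 2.0 * depth_mt_n / depth_nuc_n
    return max(0.0, (mixture_mt - (1.0 - rho) * normal_mt) / rho)
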