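"""Purity/ploidy-corrected total copy number and amplicon seed calling.

Read-depth based CNV callers report the segment log ratio
``logR = log2(tumor depth / normal depth)`` and, absent any correction,
imply a total copy number ``2 * 2**logR`` (purity 1, ploidy 2). In a
tumor sample of purity rho mixed with diploid normal cells, with tumor
ploidy psi, the tumor-cell total copy number is instead

    TCN = (psi * 2**logR - 2 * (1 - rho)) / rho

Low-purity samples dilute amplifications toward copy number 2, so the
uncorrected estimate misses high-copy segments that the corrected one
recovers; seed calling on corrected TCN is what makes amplicon detection
purity-independent.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import CNSegment, SamplePloidyModel, SeedRegion

__all__ = [
    "rescale_total_copy_number",
    "uncorrected_total_copy_number",
    "annotate_segments",
    "call_seed_regions",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_CN = 4.5
DEFAULT_MIN_LEN = 50_000
DEFAULT_MERGE_GAP = 300_000


def rescale_total_copy_number(logr, model: SamplePloidyModel):
    """Purity/ploidy-corrected total copy number for one or many logR values.

    Negative raw values (possible under noise at low purity) are clamped
    to 0; the number of clamped entries is logged at DEBUG level.
    Accepts a scalar or array-like ``logr`` and returns the same shape.
    """
    if not isinstance(model, SamplePloidyModel):
        model = SamplePloidyModel(*model)
    arr = np.asarray(logr, dtype=float)
    raw = (model.ploidy * np.exp2(arr) - 2.0 * (1.0 - model.purity)) / model.purity
    n_clamped = int(np.count_nonzero(raw < 0))
    if n_clamped:
        logger.debug("clamped %d negative rescaled TCN values to 0", n_clamped)
    out = np.maximum(raw, 0.0)
    return float(out) if np.isscalar(logr) else out


def uncorrected_total_copy_number(logr):
    """Naive total copy number at purity 1, ploidy 2: ``2 * 2**logR``."""
    arr = np.asarray(logr, dtype=float)
    out = 2.0 * np.exp2(arr)
    return float(out) if np.isscalar(logr) else out


def annotate_segments(
    segments: list[CNSegment], model: SamplePloidyModel
) -> list[CNSegment]:
    """Fill ``tcn`` and ``tcn_uncorrected`` on each segment in place."""
    for seg in segments:
        seg.tcn = rescale_total_copy_number(seg.logr, model)
        seg.tcn_uncorrected = uncorrected_total_copy_number(seg.logr)
    return segments


def _check_sorted(segments: list[CNSegment]) -> None:
    prev: CNSegment | None = None
    seen_chroms: set[str] = set()
    for seg in segments:
        if prev is None or seg.chrom != prev.chrom:
            if seg.chrom in seen_chroms:
                raise ValueError(f"segments not grouped by chromosome: {seg.chrom}")
            seen_chroms.add(seg.chrom)
        elif seg.start < prev.end:
            raise ValueError(
                f"segments unsorted or overlapping at {seg.chrom}:{seg.start}"
            )
        prev = seg


def call_seed_regions(
    segments: list[CNSegment],
    min_cn: float = DEFAULT_MIN_CN,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    use_uncorrected: bool = False,
) -> list[SeedRegion]:
    """Call amplicon seed regions from annotated segments.

    Maximal runs of segments with copy number >= ``min_cn`` are merged
    across gaps <= ``merge_gap`` and emitted as seeds when the merged
    span is >= ``min_len``. Input must be sorted and non-overlapping per
    chromosome (an error is raised rather than silently sorting).

    Thresholds default to the conventional AmpliconArchitect-style
    seeding values (CN 4.5, 50 kb, 300 kb merge gap).
    """
    _check_sorted(segments)

    def cn_of(seg: CNSegment) -> float:
        value = seg.tcn_uncorrected if use_uncorrected else seg.tcn
        if value is None:
            raise ValueError("segments lack copy-number annotation; "
                             "run annotate_segments first")
        return value

    # high-CN intervals per chromosome, in input order
    raw: list[list] = []  # [chrom, start, end, max_cn]
    for seg in segments:
        cn = cn_of(seg)
        if cn < min_cn:
            continue
        if raw and raw[-1][0] == seg.chrom and seg.start - raw[-1][2] <= merge_gap:
            raw[-1][2] = seg.end
            raw[-1][3] = max(raw[-1][3], cn)
        else:
            raw.append([seg.chrom, seg.start, seg.end, cn])

    seeds = [
        SeedRegion(chrom, start, end, max_tcn=max_cn)
        for chrom, start, end, max_cn in raw
        if end - start >= min_len
    ]
    seeds.sort(key=lambda s: (s.chrom, s.start))
    return seeds
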