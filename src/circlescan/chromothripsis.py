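"""High-confidence chromothripsis criteria over SV clusters and CN profiles.

A cluster is called high-confidence chromothripsis when all of the
following hold:

(i)   more than 6 clustered intrachromosomal SVs (DUP/DEL/h2hINV/t2tINV);
(ii)  more than 7 oscillations of the rounded copy number between
      exactly two states inside the cluster region;
(iii) breakpoints significantly enriched in the region (one-sided
      binomial tail p < 0.05);
(iv)  fragment joins compatible with random re-ligation (chi-square
      goodness-of-fit p > 0.05 against equal type proportions) and/or
      at least 4 interchromosomal rearrangements touching the region.

The binomial enrichment and chi-square join tests are this package's
concrete stand-ins for the corresponding statistical criteria; both are
swappable via the keyword arguments of :func:`call_chromothripsis`.
"""

from __future__ import annotations

from scipy import stats as sps

from .types import ChromothripsisCall, CNSegment, StructuralVariant

__all__ = [
    "cluster_intrachromosomal_svs",
    "count_oscillations",
    "breakpoint_enrichment_pvalue",
    "join_randomness_pvalue",
    "call_chromothripsis",
    "overlap_ecdna_chromothripsis",
]

DEFAULT_MAX_GAP = 1_000_000
MIN_CLUSTER_SV = 6  # criterion (i): strictly more than 6
MIN_OSCILLATIONS = 7  # criterion (ii): strictly more than 7
ENRICH_ALPHA = 0.05
JOIN_ALPHA = 0.05
MIN_INTERCHROM = 4

INTRA_TYPES = ("DUP", "DEL", "h2hINV", "t2tINV")


def cluster_intrachromosomal_svs(
    svs: list[StructuralVariant],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[dict]:
    """Single-linkage clustering of intrachromosomal SV breakends.

    Two SVs join the same cluster when any pair of their breakends on
    the same chromosome lies within ``max_gap``. Returns one dict per
    cluster with keys chrom, start, end, svs (member SV objects).
    """
    by_chrom: dict[str, list[StructuralVariant]] = {}
    for sv in svs:
        if sv.is_intrachromosomal and sv.svtype in INTRA_TYPES:
            by_chrom.setdefault(sv.chrom1, []).append(sv)

    clusters: list[dict] = []
    for chrom, members in sorted(by_chrom.items()):
        # single-linkage on the sorted breakend multiset: SVs whose
        # breakend intervals chain within max_gap are transitively linked
        events = sorted(
            (pos, i) for i, sv in enumerate(members) for pos in (sv.pos1, sv.pos2)
        )
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            parent[find(i)] = find(j)

        for (p1, i1), (p2, i2) in zip(events[:-1], events[1:]):
            if p2 - p1 <= max_gap:
                union(i1, i2)
        groups: dict[int, list[StructuralVariant]] = {}
        for i, sv in enumerate(members):
            groups.setdefault(find(i), []).append(sv)
        for group in groups.values():
            positions = [p for sv in group for p in (sv.pos1, sv.pos2)]
            clusters.append(
                {
                    "chrom": chrom,
                    "start": min(positions),
                    "end": max(positions),
                    "svs": group,
                }
            )
    clusters.sort(key=lambda c: (c["chrom"], c["start"]))
    return clusters


def count_oscillations(segments: list[CNSegment]) -> int:
    """Switch count of the longest two-state alternation of rounded TCN.

    Scans all sub-runs of consecutive segments whose rounded corrected
    copy number alternates between exactly two distinct values with no
    repeats and no third state, and returns the number of state
    switches in the longest such run (0 for constant or empty input).
    """
    if any(s.tcn is None for s in segments):
        raise ValueError("segments lack corrected TCN annotation")
    states = [round(s.tcn) for s in segments]
    if len(states) < 2:
        return 0
    best = 0
    n = len(states)
    for i in range(n - 1):
        if states[i + 1] == states[i]:
            continue
        a, b = states[i], states[i + 1]
        switches = 1
        expected = a
        for j in range(i + 2, n):
            if states[j] == expected:
                switches += 1
                expected = b if expected == a else a
            else:
                break
        best = max(best, switches)
    return best


def breakpoint_enrichment_pvalue(
    n_in_region: int, region_len: int, n_genome: int, genome_len: int
) -> float:
    """One-sided binomial tail P(X >= n_in_region), X ~ Bin(n_genome, L_r/L_g)."""
    if region_len <= 0 or genome_len <= 0:
        raise ValueError("lengths must be positive")
    if n_in_region > n_genome:
        raise ValueError("n_in_region cannot exceed n_genome")
    p = min(region_len / genome_len, 1.0)
    return float(sps.binom.sf(n_in_region - 1, n_genome, p))


def join_randomness_pvalue(type_counts) -> float:
    """Chi-square goodness-of-fit p against equal DUP/DEL/h2h/t2t proportions."""
    counts = list(type_counts)
    if len(counts) != 4:
        raise ValueError("expected counts for the four intrachromosomal types")
    total = sum(counts)
    if total < 1:
        raise ValueError("need at least one join")
    return float(sps.chisquare(counts).pvalue)


def call_chromothripsis(
    svs: list[StructuralVariant],
    segments: list[CNSegment],
    max_gap: int = DEFAULT_MAX_GAP,
    enrichment_test=breakpoint_enrichment_pvalue,
    join_test=join_randomness_pvalue,
) -> list[ChromothripsisCall]:
    """Evaluate the high-confidence criteria on every SV cluster of a sample.

    ``segments`` must carry corrected TCN annotation and define the
    genome extent used by the enrichment test; interchromosomal counts
    consider translocations with at least one breakend in the cluster
    region.
    """
    genome_len = sum(s.length for s in segments)
    breakends = [
        (sv.chrom1, sv.pos1) for sv in svs
    ] + [(sv.chrom2, sv.pos2) for sv in svs]
    n_genome = len(breakends)
    calls: list[ChromothripsisCall] = []
    for cluster in cluster_intrachromosomal_svs(svs, max_gap=max_gap):
        chrom, start, end = cluster["chrom"], cluster["start"], cluster["end"]
        region_len = max(end - start, 1)
        members = cluster["svs"]
        n_cluster_sv = len(members)

        region_segments = [
            s
            for s in sorted(segments, key=lambda s: (s.chrom, s.start))
            if s.chrom == chrom and s.start < end and s.end > start
        ]
        n_osc = count_oscillations(region_segments)

        n_in_region = sum(
            1 for c, p in breakends if c == chrom and start <= p <= end
        )
        p_enrich = enrichment_test(n_in_region, region_len, n_genome, genome_len)

        counts = [sum(1 for sv in members if sv.svtype == t) for t in INTRA_TYPES]
        p_joins = join_test(counts)

        n_interchrom = sum(
            1
            for sv in svs
            if sv.svtype == "TRA"
            and (
                (sv.chrom1 == chrom and start <= sv.pos1 <= end)
                or (sv.chrom2 == chrom and start <= sv.pos2 <= end)
            )
        )
        high_confidence = (
            n_cluster_sv > MIN_CLUSTER_SV
            and n_osc > MIN_OSCILLATIONS
            and p_enrich < ENRICH_ALPHA
            and (p_joins > JOIN_ALPHA or n_interchrom >= MIN_INTERCHROM)
        )
        calls.append(
            ChromothripsisCall(
                chrom=chrom,
                start=start,
                end=end,
                n_cluster_sv=n_cluster_sv,
                n_oscillations=n_osc,
                p_enrich=p_enrich,
                p_joins=p_joins,
                n_interchrom=n_interchrom,
                high_confidence=high_confidence,
            )
        )
    return calls


def overlap_ecdna_chromothripsis(
    ecdna_intervals: list[tuple[str, int, int]],
    calls: list[ChromothripsisCall],
) -> tuple[bool, int]:
    """Overlap between ecDNA intervals and high-confidence regions.

    Returns (any >=1 bp intersection, total intersected bases). Both
    interval sets are merged before intersection so subdividing either
    side cannot change the result.
    """
    from .amplicon import _merge_intervals

    ec = _merge_intervals(ecdna_intervals)
    ct = _merge_intervals(
        (c.chrom, c.start, c.end) for c in calls if c.high_confidence
    )
    total = 0
    for c1, s1, e1 in ec:
        for c2, s2, e2 in ct:
            if c1 == c2:
                total += max(0, min(e1, e2) - max(s1, s2))
    return total > 0, total
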