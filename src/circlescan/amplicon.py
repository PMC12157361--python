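"""Breakpoint-graph construction and simplified amplicon classification.

This is a deliberately simplified classifier, not a re-implementation of
full amplicon-reconstruction tools: it builds an orientation-aware
breakpoint graph over seed regions and assigns each connected amplified
component one of four formation-mechanism labels — ecDNA (a cycle
through at least one discordant junction at high copy number), BFB
(foldback-inversion dominated), complex non-cyclic, or linear (no SVs).

Graph model
-----------
Each genomic sub-interval inside a (padded) seed contributes two
*extremity* nodes, its left (L) and right (R) side. Three edge kinds
connect them:

* ``segment`` edges join the L and R extremities of one sub-interval
  (traversing the DNA of the interval);
* ``adjacency`` edges join the R extremity of one sub-interval to the L
  extremity of the next along the reference;
* ``sv`` edges realise discordant junctions: a breakend with strand
  ``+`` attaches to the R extremity of the sub-interval ending at its
  position, strand ``-`` to the L extremity of the one starting there.

A physically realisable amplicon walk alternates segment edges with
junction (adjacency or sv) edges. ecDNA corresponds to a closed
alternating walk using at least one sv edge; a lone foldback inversion
cannot close such a walk, which is what separates BFB from ecDNA here.
"""

from __future__ import annotations

import statistics

import networkx as nx

from .types import Amplicon, CNSegment, SeedRegion, StructuralVariant

__all__ = [
    "build_breakpoint_graph",
    "decompose_amplicons",
    "classify_amplicon",
    "has_discordant_cycle",
    "summarize_sample",
    "analyze_sample",
]

DEFAULT_PAD = 100_000
DEFAULT_MIN_ECDNA_CN = 4.5
DEFAULT_MIN_FOLDBACK_FRAC = 0.25
FOLDBACK_MAX_DIST = 30_000

JUNCTION_KINDS = ("adjacency", "sv")


def _merge_intervals(intervals):
    out = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1][2] = max(out[-1][2], end)
        else:
            out.append([chrom, start, end])
    return [tuple(iv) for iv in out]


def build_breakpoint_graph(
    seeds: list[SeedRegion],
    svs: list[StructuralVariant],
    segments: list[CNSegment],
    pad: int = DEFAULT_PAD,
) -> nx.MultiGraph:
    """Build the extremity graph over padded seed regions.

    Discordant (sv) edges are admitted only for SVs with *both*
    breakends inside padded seeds. Node keys are
    ``(chrom, start, end, side)`` with side in {"L", "R"}; nodes carry
    ``tcn`` (max corrected copy number of overlapping segments) and
    ``in_seed`` (overlaps an unpadded seed) attributes.
    """
    padded = _merge_intervals(
        (s.chrom, max(s.start - pad, 0), s.end + pad) for s in seeds
    )

    # boundary positions per padded interval: its ends, segment
    # boundaries, and admitted SV breakends
    def _find_interval(chrom: str, pos: int):
        for iv in padded:
            if iv[0] == chrom and iv[1] <= pos <= iv[2]:
                return iv
        return None

    def _admitted(sv: StructuralVariant) -> bool:
        return (
            _find_interval(sv.chrom1, sv.pos1) is not None
            and _find_interval(sv.chrom2, sv.pos2) is not None
        )

    admitted = [(i, sv) for i, sv in enumerate(svs) if _admitted(sv)]

    boundaries: dict[tuple, set[int]] = {iv: {iv[1], iv[2]} for iv in padded}
    for seg in segments:
        for pos in (seg.start, seg.end):
            iv = _find_interval(seg.chrom, pos)
            if iv is not None:
                boundaries[iv].add(pos)
    for _, sv in admitted:
        for chrom, pos in ((sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)):
            iv = _find_interval(chrom, pos)
            boundaries[iv].add(pos)

    graph = nx.MultiGraph()
    sub_by_start: dict[tuple, list[tuple]] = {}
    sub_by_end: dict[tuple, list[tuple]] = {}

    seg_sorted = sorted(segments, key=lambda s: (s.chrom, s.start))

    def _max_tcn(chrom: str, start: int, end: int) -> float:
        best = 0.0
        for seg in seg_sorted:
            if seg.chrom == chrom and seg.start < end and seg.end > start:
                best = max(best, seg.tcn if seg.tcn is not None else 0.0)
        return best

    seed_ivs = [(s.chrom, s.start, s.end) for s in seeds]

    def _in_seed(chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and start < e and end > s for c, s, e in seed_ivs)

    for iv in padded:
        chrom = iv[0]
        pos = sorted(boundaries[iv])
        for lo, hi in zip(pos[:-1], pos[1:]):
            sub = (chrom, lo, hi)
            attrs = dict(
                tcn=_max_tcn(chrom, lo, hi), in_seed=_in_seed(chrom, lo, hi)
            )
            graph.add_node((*sub, "L"), **attrs)
            graph.add_node((*sub, "R"), **attrs)
            graph.add_edge((*sub, "L"), (*sub, "R"), kind="segment")
            sub_by_start.setdefault((chrom, lo), []).append(sub)
            sub_by_end.setdefault((chrom, hi), []).append(sub)
        for lo, hi in zip(pos[:-1], pos[1:]):
            nxt = [s for s in sub_by_start.get((chrom, hi), []) if s[1] == hi]
            for s in nxt:
                graph.add_edge((chrom, lo, hi, "R"), (*s, "L"), kind="adjacency")

    def _attach(chrom: str, p: int, strand: str):
        if strand == "+":
            subs = sub_by_end.get((chrom, p), [])
            return (*subs[0], "R") if subs else None
        subs = sub_by_start.get((chrom, p), [])
        return (*subs[0], "L") if subs else None

    for idx, sv in admitted:
        u = _attach(sv.chrom1, sv.pos1, sv.strand1)
        v = _attach(sv.chrom2, sv.pos2, sv.strand2)
        if u is None or v is None:
            continue  # breakend at the outer pad boundary with no flank
        graph.add_edge(u, v, kind="sv", sv_index=idx,
                       foldback=sv.is_foldback(FOLDBACK_MAX_DIST))
    return graph


def has_discordant_cycle(graph: nx.MultiGraph) -> bool:
    """True iff a closed alternating (segment/junction) walk uses an sv edge.

    Searches the directed state graph on (extremity, next-edge-kind)
    pairs: a state lies on a cycle iff it belongs to a non-trivial
    strongly connected component, and the cycle uses a discordant edge
    iff some sv-edge transition stays inside one such component.
    """
    state = nx.DiGraph()
    sv_transitions = []
    for u, v, data in graph.edges(data=True):
        if data["kind"] == "segment":
            state.add_edge((u, "seg"), (v, "junc"))
            state.add_edge((v, "seg"), (u, "junc"))
        else:
            state.add_edge((u, "junc"), (v, "seg"))
            state.add_edge((v, "junc"), (u, "seg"))
            if data["kind"] == "sv":
                sv_transitions.append(((u, "junc"), (v, "seg")))
                sv_transitions.append(((v, "junc"), (u, "seg")))
    scc_of = {}
    for k, comp in enumerate(nx.strongly_connected_components(state)):
        for node in comp:
            scc_of[node] = k
    return any(
        a in scc_of and b in scc_of and scc_of[a] == scc_of[b]
        for a, b in sv_transitions
    )


def classify_amplicon(
    amp: Amplicon,
    min_ecdna_cn: float = DEFAULT_MIN_ECDNA_CN,
    min_foldback_frac: float = DEFAULT_MIN_FOLDBACK_FRAC,
) -> str:
    """Assign a formation-mechanism class to one amplicon.

    ecDNA requires a discordant cycle at copy number >= ``min_ecdna_cn``
    (ties between the cycle and foldback evidence resolve to ecDNA);
    BFB requires foldback junctions to make up >= ``min_foldback_frac``
    of the component's SVs; any other rearranged component is complex
    non-cyclic, and SV-free components are linear.
    """
    if amp.graph is None:
        raise ValueError("amplicon carries no graph; use decompose_amplicons")
    sv_edges = [
        data for _, _, data in amp.graph.edges(data=True) if data["kind"] == "sv"
    ]
    if sv_edges and has_discordant_cycle(amp.graph) and amp.max_cn >= min_ecdna_cn:
        return "ecDNA"
    if sv_edges:
        foldback_frac = sum(bool(d.get("foldback")) for d in sv_edges) / len(sv_edges)
        if foldback_frac >= min_foldback_frac:
            return "BFB"
        return "complex_noncyclic"
    return "linear"


def decompose_amplicons(
    graph: nx.MultiGraph,
    min_ecdna_cn: float = DEFAULT_MIN_ECDNA_CN,
    min_foldback_frac: float = DEFAULT_MIN_FOLDBACK_FRAC,
) -> list[Amplicon]:
    """One classified amplicon per connected component containing a seed."""
    amps: list[Amplicon] = []
    for comp_nodes in nx.connected_components(graph):
        sub = graph.subgraph(comp_nodes)
        seed_subs = {
            (n[0], n[1], n[2]) for n in comp_nodes if sub.nodes[n]["in_seed"]
        }
        if not seed_subs:
            continue
        intervals = _merge_intervals(seed_subs)
        tcns = [
            sub.nodes[(*s, "L")]["tcn"] for s in seed_subs
        ]
        sv_indices = sorted(
            {
                data["sv_index"]
                for _, _, data in sub.edges(data=True)
                if data["kind"] == "sv"
            }
        )
        amp = Amplicon(
            id="",
            intervals=intervals,
            sv_indices=sv_indices,
            max_cn=max(tcns),
            median_cn=float(statistics.median(tcns)),
            graph=sub,
        )
        amp.cls = classify_amplicon(amp, min_ecdna_cn, min_foldback_frac)
        amps.append(amp)
    amps.sort(key=lambda a: a.intervals[0])
    for k, amp in enumerate(amps, start=1):
        amp.id = f"amp_{k}"
    return amps


def summarize_sample(amps: list[Amplicon]) -> dict:
    """Per-sample counts; one or more ecDNA makes the sample ecDNA-positive."""
    counts = {"ecDNA": 0, "BFB": 0, "complex_noncyclic": 0, "linear": 0}
    for amp in amps:
        counts[amp.cls] += 1
    return {
        "ecdna_count": counts["ecDNA"],
        "ecdna_positive": counts["ecDNA"] >= 1,
        "class_counts": counts,
    }


def analyze_sample(
    segments: list[CNSegment],
    svs: list[StructuralVariant],
    model,
    min_cn: float | None = None,
    pad: int = DEFAULT_PAD,
    use_uncorrected: bool = False,
) -> tuple[list[Amplicon], dict]:
    """Segments + SVs -> annotated seeds -> classified amplicons -> summary."""
    from . import copy_number as cn

    cn.annotate_segments(segments, model)
    kwargs = {} if min_cn is None else {"min_cn": min_cn}
    seeds = cn.call_seed_regions(segments, use_uncorrected=use_uncorrected, **kwargs)
    graph = build_breakpoint_graph(seeds, svs, segments, pad=pad)
    amps = decompose_amplicons(graph)
    return amps, summarize_sample(amps)
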