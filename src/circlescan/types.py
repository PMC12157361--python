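"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout (BED convention). Copy
numbers are kept as floats wherever the downstream rule does not demand
integers; rounding happens only inside the rules that require it (WGD,
wGII, oscillation counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SamplePloidyModel",
    "CNSegment",
    "StructuralVariant",
    "SeedRegion",
    "Amplicon",
    "ChromothripsisCall",
    "InstabilityMetrics",
    "ReadGroupTelomere",
    "GeneAnnotation",
    "MutationRecord",
    "CargoClass",
    "infer_svtype",
]

SV_TYPES = ("DUP", "DEL", "h2hINV", "t2tINV", "TRA")

#: strand-pair -> svtype for intrachromosomal records with pos1 <= pos2.
#: (+,-) joins a left-facing head to a right-facing tail: deletion-like.
#: (-,+) joins back upstream: tandem-duplication-like (cycle-closing).
_STRAND_TO_TYPE = {
    ("+", "-"): "DEL",
    ("-", "+"): "DUP",
    ("+", "+"): "h2hINV",
    ("-", "-"): "t2tINV",
}


def infer_svtype(chrom1: str, strand1: str, chrom2: str, strand2: str) -> str:
    """Breakend orientation -> SV type under the standard BEDPE convention."""
    if chrom1 != chrom2:
        return "TRA"
    try:
        return _STRAND_TO_TYPE[(strand1, strand2)]
    except KeyError:
        raise ValueError(f"invalid strand pair ({strand1!r}, {strand2!r})")


@dataclass(frozen=True)
class SamplePloidyModel:
    """Per-sample tumor purity (rho) and ploidy (psi) used by the rescaling."""

    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")
        if not self.ploidy > 0.0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")


@dataclass
class CNSegment:
    """One copy-number segment.

    ``logr`` is log2(tumor depth / normal depth) for the segment;
    ``tcn`` is the purity/ploidy-corrected total copy number and
    ``tcn_uncorrected`` the naive estimate at purity 1, ploidy 2.
    """

    chrom: str
    start: int
    end: int
    logr: float
    major_cn: int = 1
    minor_cn: int = 1
    tcn: float | None = None
    tcn_uncorrected: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.major_cn < self.minor_cn:
            raise ValueError("major_cn must be >= minor_cn")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class StructuralVariant:
    """One breakend pair; svtype derives from orientations when omitted."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    svtype: str = ""
    name: str = "."

    def __post_init__(self) -> None:
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            raise ValueError("intrachromosomal SV must have pos1 <= pos2")
        inferred = infer_svtype(self.chrom1, self.strand1, self.chrom2, self.strand2)
        if not self.svtype:
            object.__setattr__(self, "svtype", inferred)
        elif self.svtype != inferred:
            raise ValueError(
                f"svtype {self.svtype!r} inconsistent with strands "
                f"({self.strand1}, {self.strand2}) -> {inferred}"
            )

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def span(self) -> int:
        if not self.is_intrachromosomal:
            raise ValueError("span undefined for interchromosomal SV")
        return self.pos2 - self.pos1

    def is_foldback(self, max_dist: int = 30_000) -> bool:
        """Inverted (h2h/t2t) junction with nearby breakends."""
        return (
            self.is_intrachromosomal
            and self.svtype in ("h2hINV", "t2tINV")
            and self.span <= max_dist
        )


@dataclass(frozen=True)
class SeedRegion:
    """High-copy interval used to initiate amplicon reconstruction."""

    chrom: str
    start: int
    end: int
    max_tcn: float

    @property
    def length(self) -> int:
        return self.end - self.start


AMPLICON_CLASSES = ("ecDNA", "BFB", "complex_noncyclic", "linear")


@dataclass
class Amplicon:
    """A connected amplified region with its inferred formation mechanism."""

    id: str
    intervals: list[tuple[str, int, int]]
    sv_indices: list[int]
    cls: str = ""
    max_cn: float = 0.0
    median_cn: float = 0.0
    graph: object = field(default=None, repr=False, compare=False)


@dataclass
class ChromothripsisCall:
    chrom: str
    start: int
    end: int
    n_cluster_sv: int
    n_oscillations: int
    p_enrich: float
    p_joins: float
    n_interchrom: int
    high_confidence: bool


@dataclass
class InstabilityMetrics:
    is_wgd: bool
    wgii: float
    ploidy_lw: float
    tl_tumor_kb: float | None = None
    tl_normal_kb: float | None = None
    tl_log2_ratio: float | None = None
    mt_cn: float | None = None


@dataclass(frozen=True)
class ReadGroupTelomere:
    group_id: str
    n_reads: int
    n_telomeric: int

    def __post_init__(self) -> None:
        if self.n_telomeric > self.n_reads:
            raise ValueError("n_telomeric cannot exceed n_reads")

    def tl_kb(self, c: float = 1.0) -> float:
        if self.n_reads == 0:
            raise ValueError("read group has zero reads")
        return c * self.n_telomeric / self.n_reads


@dataclass(frozen=True)
class GeneAnnotation:
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    is_oncogene: bool = False
    is_immunomodulatory: bool = False
    is_tumor_suppressor: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty gene interval {self.name}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    consequence: str  # truncating | missense | other
    recurrence_count: int = 1
    boostdm_score: float | None = None
    oncokb_label: str | None = None
    mc3_flag: bool = False
    pathogenicity_label: str | None = None

    def __post_init__(self) -> None:
        if self.recurrence_count < 1:
            raise ValueError("recurrence_count must be >= 1")


@dataclass
class CargoClass:
    """Per-ecDNA genetic-content flags; ``unknown`` when nothing matched."""

    has_oncogene: bool = False
    has_immunomodulatory: bool = False
    has_other_gene: bool = False
    has_enhancer: bool = False
    has_promoter: bool = False

    @property
    def unknown(self) -> bool:
        return not (
            self.has_oncogene
            or self.has_immunomodulatory
            or self.has_other_gene
            or self.has_enhancer
            or self.has_promoter
        )
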