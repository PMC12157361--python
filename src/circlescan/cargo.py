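"""ecDNA genetic-cargo annotation and driver-mutation classification.

Cargo rules: a gene or enhancer counts as carried only when 100%
contained in the (merged) ecDNA intervals; promoters count on any
overlap. An ecDNA is labelled immunomodulatory only when it carries an
immunomodulatory gene and no oncogene; the final category follows the
priority oncogene > immunomodulatory > other gene > regulatory-only >
unknown.

Driver mutations: a mutation is a potential driver when it meets any of
six criteria — truncating in a tumor suppressor; missense recurring in
>= 3 samples; boostDM score > 0.5; OncoKB "Oncogenic"/"Likely
Oncogenic"; flagged in the TCGA MC3 driver catalogue; or missense
"likely pathogenic" in a tumor suppressor.

The oncogene/tumor-suppressor rosters, the immunomodulatory gene set
and enhancer intervals are caller-supplied inputs; no live database
queries happen here.
"""

from __future__ import annotations

from .types import CargoClass, GeneAnnotation, MutationRecord

__all__ = [
    "promoter_regions",
    "annotate_ecdna",
    "classify_cargo",
    "classify_driver_mutation",
]

PROMOTER_BP = 1_000

ONCOKB_DRIVER_LABELS = frozenset({"Oncogenic", "Likely Oncogenic"})


def promoter_regions(
    genes: list[GeneAnnotation],
    chrom_lengths: dict[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """1000 bp upstream of each transcription start site, strand-aware.

    Plus-strand genes get [start-1000, start), minus-strand genes
    [end, end+1000); intervals are clipped at chromosome bounds when
    lengths are provided (and at 0 always).
    """
    out = []
    for gene in genes:
        if gene.strand == "+":
            lo, hi = max(gene.start - PROMOTER_BP, 0), gene.start
        else:
            lo, hi = gene.end, gene.end + PROMOTER_BP
            if chrom_lengths is not None and gene.chrom in chrom_lengths:
                hi = min(hi, chrom_lengths[gene.chrom])
        if lo < hi:
            out.append((gene.chrom, lo, hi))
    return out


def _merge(intervals):
    out = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1][2] = max(out[-1][2], end)
        else:
            out.append([chrom, start, end])
    return out


def _contained(chrom: str, start: int, end: int, merged) -> bool:
    return any(c == chrom and s <= start and end <= e for c, s, e in merged)


def _overlaps(chrom: str, start: int, end: int, merged) -> bool:
    return any(c == chrom and start < e and end > s for c, s, e in merged)


def annotate_ecdna(
    ecdna_intervals: list[tuple[str, int, int]],
    genes: list[GeneAnnotation],
    enhancers: list[tuple[str, int, int]],
    promoters: list[tuple[str, int, int]],
    gene_containment: bool = True,
) -> CargoClass:
    """Flag the genetic content of one ecDNA.

    ecDNA intervals are merged before testing so containment is stable
    under interval subdivision. ``gene_containment=False`` relaxes the
    gene rule to >= 1 bp overlap (enhancers always require containment).
    """
    merged = _merge(ecdna_intervals)
    cargo = CargoClass()
    test_gene = _contained if gene_containment else _overlaps
    for gene in genes:
        if not test_gene(gene.chrom, gene.start, gene.end, merged):
            continue
        if gene.is_oncogene:
            cargo.has_oncogene = True
        elif gene.is_immunomodulatory:
            cargo.has_immunomodulatory = True
        else:
            cargo.has_other_gene = True
    if cargo.has_oncogene:
        # an ecDNA carrying an oncogene is never counted as immunomodulatory
        cargo.has_immunomodulatory = False
    cargo.has_enhancer = any(
        _contained(c, s, e, merged) for c, s, e in enhancers
    )
    cargo.has_promoter = any(_overlaps(c, s, e, merged) for c, s, e in promoters)
    return cargo


CARGO_CATEGORIES = (
    "oncogene",
    "immunomodulatory",
    "other_gene",
    "regulatory_only",
    "unknown",
)


def classify_cargo(cargo: CargoClass) -> str:
    """Collapse cargo flags to a single category by priority."""
    if cargo.has_oncogene:
        return "oncogene"
    if cargo.has_immunomodulatory:
        return "immunomodulatory"
    if cargo.has_other_gene:
        return "other_gene"
    if cargo.has_enhancer or cargo.has_promoter:
        return "regulatory_only"
    return "unknown"


def classify_driver_mutation(m: MutationRecord, gene: GeneAnnotation) -> bool:
    """True when the mutation meets one or more of the six driver criteria."""
    if m.consequence == "truncating" and gene.is_tumor_suppressor:
        return True
    if m.consequence == "missense" and m.recurrence_count >= 3:
        return True
    if m.boostdm_score is not None and m.boostdm_score > 0.5:
        return True
    if m.oncokb_label in ONCOKB_DRIVER_LABELS:
        return True
    if m.mc3_flag:
        return True
    if (
        m.consequence == "missense"
        and m.pathogenicity_label == "likely pathogenic"
        and gene.is_tumor_suppressor
    ):
        return True
    return False
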