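"""Readers and writers for the pipeline's plain-text table formats.

All coordinates are 0-based half-open. Formats:

* ``segments.tsv``  — chrom, start, end, logR, major_cn, minor_cn
* ``sv.bedpe``      — chrom1, start1, end1, chrom2, start2, end2, name,
  score, strand1, strand2, svtype
* ``samples.tsv``   — sample_id, purity, ploidy, covariates, time, event
* ``seeds.bed``     — chrom, start, end, name, max_tcn
* ``truth.json``    — per-sample ground-truth labels from the simulator
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import CNSegment, SeedRegion, StructuralVariant

__all__ = [
    "read_segments",
    "write_segments",
    "read_svs",
    "write_svs",
    "write_seeds",
    "write_cohort",
    "read_sample_meta",
]

SEGMENT_COLUMNS = ["chrom", "start", "end", "logR", "major_cn", "minor_cn"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "svtype",
]


def read_segments(path) -> list[CNSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        CNSegment(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            logr=float(row.logR),
            major_cn=int(row.major_cn),
            minor_cn=int(row.minor_cn),
        )
        for row in df.itertuples()
    ]


def write_segments(segments: list[CNSegment], path) -> None:
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "logR": [s.logr for s in segments],
            "major_cn": [s.major_cn for s in segments],
            "minor_cn": [s.minor_cn for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_svs(path) -> list[StructuralVariant]:
    df = pd.read_csv(path, sep="\t")
    return [
        StructuralVariant(
            chrom1=row.chrom1,
            pos1=int(row.start1),
            strand1=row.strand1,
            chrom2=row.chrom2,
            pos2=int(row.start2),
            strand2=row.strand2,
            svtype=row.svtype,
            name=str(row.name_) if hasattr(row, "name_") else str(row.name),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples()
    ]


def write_svs(svs: list[StructuralVariant], path) -> None:
    pd.DataFrame(
        {
            "chrom1": [v.chrom1 for v in svs],
            "start1": [v.pos1 for v in svs],
            "end1": [v.pos1 + 1 for v in svs],
            "chrom2": [v.chrom2 for v in svs],
            "start2": [v.pos2 for v in svs],
            "end2": [v.pos2 + 1 for v in svs],
            "name": [v.name for v in svs],
            "score": [0] * len(svs),
            "strand1": [v.strand1 for v in svs],
            "strand2": [v.strand2 for v in svs],
            "svtype": [v.svtype for v in svs],
        }
    ).to_csv(path, sep="\t", index=False)


def write_seeds(seeds: list[SeedRegion], path) -> None:
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in seeds],
            "start": [s.start for s in seeds],
            "end": [s.end for s in seeds],
            "name": [f"seed_{i + 1}" for i in range(len(seeds))],
            "max_tcn": [s.max_tcn for s in seeds],
        }
    ).to_csv(path, sep="\t", index=False, header=False)


def read_sample_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort, outdir) -> None:
    """Write a simulated cohort to ``outdir`` (one directory per sample)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = cohort.clinical.copy()
    samples["ploidy"] = [p.model.ploidy for p in cohort.profiles]
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth = {}
    for profile in cohort.profiles:
        sdir = outdir / profile.sample_id
        sdir.mkdir(exist_ok=True)
        write_segments(profile.to_cn_segments(), sdir / "segments.tsv")
        write_svs(profile.svs, sdir / "sv.bedpe")
        truth[profile.sample_id] = {
            "is_wgd": profile.truth.is_wgd,
            "has_ecdna": profile.truth.has_ecdna,
            "has_bfb": profile.truth.has_bfb,
            "has_chromothripsis": profile.truth.has_chromothripsis,
            "amplicons": profile.truth.amplicons,
            "chromothripsis_regions": [
                list(r) for r in profile.truth.chromothripsis_regions
            ],
        }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
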