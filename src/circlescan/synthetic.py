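"""Synthetic WGS cohort generator with ground-truth labels.

Emulates the statistical structure the analysis pipeline assumes:

* per-sample copy-number segment profiles diluted by tumor purity, with
  ``logR = log2((rho * TCN + 2 * (1 - rho)) / psi) + N(0, sd)`` — the
  exact algebraic inverse of the purity/ploidy rescaling, so that with
  zero noise the corrected pipeline recovers true TCN to machine
  precision;
* whole-genome doubled samples (baseline major copy number doubled);
* focal amplifications that are cyclic (ecDNA-like, one cycle-closing
  duplication junction), foldback (BFB-like, paired head-to-head
  inversions at one boundary) or linear (no SV);
* chromothripsis clusters: confined windows of oscillating two-state
  copy number with a burst of clustered SVs plus interchromosomal
  rearrangements into other chromosomes;
* read-group telomere counts and per-sample clinical covariates with
  injected logistic (WGD -> ecDNA odds ratio) and Cox (ecDNA hazard
  ratio) effect sizes.

All randomness flows from one seeded ``numpy`` generator derived from
``SimulationConfig.rng_seed``; identical configurations produce
byte-identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .types import CNSegment, SamplePloidyModel, StructuralVariant

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SampleProfile",
    "Cohort",
    "simulate_segment_profile",
    "inject_focal_amplicon",
    "inject_chromothripsis",
    "inject_background_svs",
    "simulate_clinical",
    "simulate_cohort",
    "simulate_telomere_readgroups",
]

DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i}", 10_000_000) for i in range(1, 23)
)

#: strand pairs realising each intrachromosomal join type
_TYPE_STRANDS = {
    "DUP": ("-", "+"),
    "DEL": ("+", "-"),
    "h2hINV": ("+", "+"),
    "t2tINV": ("-", "-"),
}
JOIN_TYPES = tuple(_TYPE_STRANDS)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Effect sizes default to the injected truths the statistics layer is
    asked to recover: an odds ratio of 4.0 for WGD -> ecDNA presence and
    a hazard ratio of 2.17 for ecDNA-positive versus other-focal
    survival. The ecDNA prevalence defaults to 18.9% and the baseline
    genome is 22 toy autosomes of 10 Mb each (hg38-scale lengths can be
    passed instead).
    """

    n_samples: int = 200
    purity_range: tuple[float, float] = (0.2, 0.95)
    wgd_fraction: float = 0.40
    ecdna_fraction: float = 0.189
    bfb_fraction: float = 0.08
    linear_amp_fraction: float = 0.15
    chromothripsis_fraction: float = 0.25
    logr_noise_sd: float = 0.02
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    effect_or_wgd_ecdna: float = 4.0
    effect_hr_ecdna: float = 2.17
    censoring_rate: float = 0.30
    n_background_sv: int = 20
    amplicon_cn: float = 20.0
    amplicon_len: int = 1_000_000
    bfb_cn: float = 12.0
    linear_cn: float = 8.0
    chromothripsis_n_sv: int = 14
    chromothripsis_n_tra: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 < low <= high <= 1")
        for name in (
            "wgd_fraction",
            "ecdna_fraction",
            "bfb_fraction",
            "linear_amp_fraction",
            "chromothripsis_fraction",
            "censoring_rate",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.logr_noise_sd < 0:
            raise ValueError("logr_noise_sd must be non-negative")
        if self.effect_or_wgd_ecdna <= 0 or self.effect_hr_ecdna <= 0:
            raise ValueError("effect sizes must be positive")

    @property
    def genome_dict(self) -> dict[str, int]:
        return dict(self.genome)


@dataclass
class GroundTruth:
    """Per-sample injected-event labels and loci."""

    is_wgd: bool = False
    has_ecdna: bool = False
    has_bfb: bool = False
    has_chromothripsis: bool = False
    amplicons: list[dict] = field(default_factory=list)
    chromothripsis_regions: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SimSegment:
    """Generator-internal segment carrying the true (undiluted) TCN."""

    chrom: str
    start: int
    end: int
    tcn: float
    major: int
    minor: int
    eps: float = 0.0
    logr: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


def _forward_logr(tcn: float, model: SamplePloidyModel) -> float:
    mixture = model.purity * tcn + 2.0 * (1.0 - model.purity)
    return math.log2(mixture / model.ploidy)


@dataclass
class SampleProfile:
    sample_id: str
    genome: dict[str, int]
    model: SamplePloidyModel
    segments: list[SimSegment]
    svs: list[StructuralVariant] = field(default_factory=list)
    truth: GroundTruth = field(default_factory=GroundTruth)
    noise_sd: float = 0.0

    def recompute_logr(self) -> None:
        for seg in self.segments:
            seg.logr = _forward_logr(seg.tcn, self.model) + seg.eps

    def to_cn_segments(self) -> list[CNSegment]:
        return [
            CNSegment(
                chrom=s.chrom,
                start=s.start,
                end=s.end,
                logr=s.logr,
                major_cn=s.major,
                minor_cn=s.minor,
            )
            for s in self.segments
        ]

    def segment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "logR": [s.logr for s in self.segments],
                "major_cn": [s.major for s in self.segments],
                "minor_cn": [s.minor for s in self.segments],
            }
        )

    def sv_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom1": [v.chrom1 for v in self.svs],
                "start1": [v.pos1 for v in self.svs],
                "end1": [v.pos1 + 1 for v in self.svs],
                "chrom2": [v.chrom2 for v in self.svs],
                "start2": [v.pos2 for v in self.svs],
                "end2": [v.pos2 + 1 for v in self.svs],
                "name": [v.name for v in self.svs],
                "score": [0] * len(self.svs),
                "strand1": [v.strand1 for v in self.svs],
                "strand2": [v.strand2 for v in self.svs],
                "svtype": [v.svtype for v in self.svs],
            }
        )

    def split_at(self, chrom: str, pos: int) -> None:
        """Split the segment containing ``pos`` (no-op on a boundary)."""
        out: list[SimSegment] = []
        for seg in self.segments:
            if seg.chrom == chrom and seg.start < pos < seg.end:
                out.append(replace(seg, end=pos))
                out.append(replace(seg, start=pos))
            else:
                out.append(seg)
        self.segments = out


def simulate_segment_profile(
    cfg: SimulationConfig,
    sample_idx: int,
    rng: np.random.Generator,
    purity: float | None = None,
    wgd: bool | None = None,
) -> SampleProfile:
    """Simulate one baseline (pre-injection) segment profile.

    Chromosomes are tiled gap-free with 3-8 segments each; roughly a
    quarter of segments carry a single-copy arm-level aberration. Gains
    in whole-genome-doubled samples are skipped so that no baseline
    segment reaches the focal-amplification range: injected events alone
    determine a sample's amplicon ground truth.
    """
    if purity is None:
        purity = float(rng.uniform(*cfg.purity_range))
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    if wgd is None:
        wgd = bool(rng.random() < cfg.wgd_fraction)

    base = 2 if wgd else 1  # per-allele baseline
    segments: list[SimSegment] = []
    for chrom, length in cfg.genome:
        n_seg = int(rng.integers(3, 9))
        cuts = np.sort(rng.choice(np.arange(1, length // 10_000), size=n_seg - 1,
                                  replace=False)) * 10_000
        bounds = [0, *cuts.tolist(), length]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            major, minor = base, base
            if rng.random() < 0.25:
                delta = int(rng.choice([-1, 1]))
                if wgd and delta > 0:
                    delta = -1  # cap gains below the seeding range
                major += delta
                if major < minor:
                    major, minor = minor, major
                if major + minor == 0:
                    major = 1  # keep at least one copy
            segments.append(
                SimSegment(
                    chrom=chrom,
                    start=int(lo),
                    end=int(hi),
                    tcn=float(major + minor),
                    major=major,
                    minor=minor,
                    eps=float(rng.normal(0.0, cfg.logr_noise_sd))
                    if cfg.logr_noise_sd > 0
                    else 0.0,
                )
            )

    total = sum(s.length for s in segments)
    ploidy = sum(s.length * s.tcn for s in segments) / total
    model = SamplePloidyModel(purity=purity, ploidy=ploidy)
    profile = SampleProfile(
        sample_id=f"S{sample_idx:04d}",
        genome=cfg.genome_dict,
        model=model,
        segments=segments,
        truth=GroundTruth(is_wgd=wgd),
        noise_sd=cfg.logr_noise_sd,
    )
    profile.recompute_logr()
    return profile


def inject_focal_amplicon(
    profile: SampleProfile,
    locus: tuple[str, int, int],
    cn: float,
    kind: str,
    rng: np.random.Generator,
) -> list[StructuralVariant]:
    """Raise ``locus`` to copy number ``cn`` and add kind-specific SVs.

    ``cyclic`` adds one head-to-tail (duplication-like) junction joining
    the locus end back to its start; ``foldback`` adds two head-to-head
    inversions at the left boundary; ``linear`` adds no SV. logR on the
    locus is re-emitted through the forward model with the profile's
    recorded ploidy (ploidy stays at its baseline estimate, as a real
    purity/ploidy caller would report it).
    """
    chrom, start, end = locus
    if chrom not in profile.genome:
        raise ValueError(f"chromosome {chrom} absent from genome")
    if not (0 <= start < end <= profile.genome[chrom]):
        raise ValueError(f"locus {chrom}:{start}-{end} outside genome bounds")
    if kind not in ("cyclic", "foldback", "linear"):
        raise ValueError(f"unknown amplicon kind {kind!r}")
    baseline = 4.0 if profile.truth.is_wgd else 2.0
    if cn <= baseline:
        raise ValueError(f"amplicon cn {cn} not above sample baseline {baseline}")

    profile.split_at(chrom, start)
    profile.split_at(chrom, end)
    for seg in profile.segments:
        if seg.chrom == chrom and seg.start >= start and seg.end <= end:
            seg.tcn = float(cn)
            seg.major = max(int(round(cn)) - seg.minor, seg.minor)
            seg.logr = _forward_logr(seg.tcn, profile.model) + seg.eps

    new_svs: list[StructuralVariant] = []
    if kind == "cyclic":
        new_svs.append(
            StructuralVariant(chrom, start, "-", chrom, end, "+",
                              name="ecdna_junction")
        )
    elif kind == "foldback":
        # two head-to-head inversions at the left boundary, breakend
        # spacing well under the 30 kb foldback-detection distance
        for k, (o1, o2) in enumerate(((1_000, 6_000), (2_500, 9_500))):
            new_svs.append(
                StructuralVariant(
                    chrom, start + o1, "+", chrom, min(start + o2, end - 1), "+",
                    name=f"bfb_foldback_{k}",
                )
            )
    profile.svs.extend(new_svs)
    profile.truth.amplicons.append(
        {"chrom": chrom, "start": start, "end": end, "cn": cn, "kind": kind}
    )
    if kind == "cyclic":
        profile.truth.has_ecdna = True
    elif kind == "foldback":
        profile.truth.has_bfb = True
    return new_svs


def inject_chromothripsis(
    profile: SampleProfile,
    chrom: str,
    n_sv: int,
    rng: np.random.Generator,
    n_tra: int = 0,
    window_len: int = 3_000_000,
) -> list[StructuralVariant]:
    """Inject a chromothripsis-like event on ``chrom``.

    The copy-number profile inside a confined window is replaced by
    ``n_sv`` segments oscillating between the baseline state and one
    copy below it (n_sv - 1 switches), and ``n_sv`` intrachromosomal SVs
    with join type drawn uniformly from DUP/DEL/h2hINV/t2tINV are placed
    in the window. ``n_tra`` additional translocations connect the
    window to other chromosomes, mirroring the multi-chromosome reach of
    real chromothripsis.
    """
    if chrom not in profile.genome:
        raise ValueError(f"chromosome {chrom} absent from genome")
    if n_sv < 1:
        raise ValueError("n_sv must be >= 1")
    length = profile.genome[chrom]
    window_len = min(window_len, length)
    w_start = int(rng.integers(0, length - window_len + 1))
    w_end = w_start + window_len

    profile.split_at(chrom, w_start)
    profile.split_at(chrom, w_end)
    kept = [
        s
        for s in profile.segments
        if not (s.chrom == chrom and s.start >= w_start and s.end <= w_end)
    ]
    base = 4.0 if profile.truth.is_wgd else 2.0
    low = max(base - 1.0, 1.0)
    n_seg = max(n_sv, 2)
    bounds = np.linspace(w_start, w_end, n_seg + 1).astype(int)
    oscillating = []
    for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        tcn = base if i % 2 == 0 else low
        minor = int(tcn) // 2
        oscillating.append(
            SimSegment(
                chrom=chrom,
                start=int(lo),
                end=int(hi),
                tcn=float(tcn),
                major=int(tcn) - minor,
                minor=minor,
                eps=float(rng.normal(0.0, profile.noise_sd))
                if profile.noise_sd > 0
                else 0.0,
            )
        )
    profile.segments = sorted(
        kept + oscillating, key=lambda s: (_chrom_rank(profile, s.chrom), s.start)
    )
    for seg in oscillating:
        seg.logr = _forward_logr(seg.tcn, profile.model) + seg.eps

    new_svs: list[StructuralVariant] = []
    for k in range(n_sv):
        p1, p2 = sorted(
            int(x) for x in rng.integers(w_start, w_end, size=2)
        )
        if p1 == p2:
            p2 += 1
        svtype = JOIN_TYPES[int(rng.integers(0, 4))]
        s1, s2 = _TYPE_STRANDS[svtype]
        new_svs.append(
            StructuralVariant(chrom, p1, s1, chrom, p2, s2, name=f"ct_sv_{k}")
        )
    others = [c for c in profile.genome if c != chrom]
    intra_breakends = sorted(p for sv in new_svs for p in (sv.pos1, sv.pos2))
    for k in range(n_tra):
        chrom2 = others[int(rng.integers(0, len(others)))]
        # translocations emanate from the shattered fragment junctions
        p1 = int(intra_breakends[int(rng.integers(0, len(intra_breakends)))])
        p2 = int(rng.integers(0, profile.genome[chrom2]))
        s1 = "+" if rng.random() < 0.5 else "-"
        s2 = "+" if rng.random() < 0.5 else "-"
        new_svs.append(
            StructuralVariant(chrom, p1, s1, chrom2, p2, s2, name=f"ct_tra_{k}")
        )
    profile.svs.extend(new_svs)
    profile.truth.has_chromothripsis = True
    profile.truth.chromothripsis_regions.append((chrom, w_start, w_end))
    return new_svs


def _chrom_rank(profile: SampleProfile, chrom: str) -> int:
    return list(profile.genome).index(chrom)


def inject_background_svs(
    profile: SampleProfile,
    n: int,
    rng: np.random.Generator,
    exclude_chroms: set[str] | None = None,
) -> list[StructuralVariant]:
    """Scatter ``n`` unclustered SVs over chromosomes without injected events."""
    exclude = exclude_chroms or set()
    allowed = [c for c in profile.genome if c not in exclude]
    if not allowed:
        return []
    new_svs: list[StructuralVariant] = []
    for k in range(n):
        if rng.random() < 0.8:
            chrom = allowed[int(rng.integers(0, len(allowed)))]
            length = profile.genome[chrom]
            span = int(rng.integers(50_000, 5_000_000))
            p1 = int(rng.integers(0, max(length - span, 1)))
            svtype = JOIN_TYPES[int(rng.integers(0, 4))]
            s1, s2 = _TYPE_STRANDS[svtype]
            new_svs.append(
                StructuralVariant(chrom, p1, s1, chrom, min(p1 + span, length - 1),
                                  s2, name=f"background_{k}")
            )
        else:
            c1, c2 = rng.choice(len(allowed), size=2, replace=False)
            chrom1, chrom2 = allowed[int(c1)], allowed[int(c2)]
            new_svs.append(
                StructuralVariant(
                    chrom1,
                    int(rng.integers(0, profile.genome[chrom1])),
                    "+" if rng.random() < 0.5 else "-",
                    chrom2,
                    int(rng.integers(0, profile.genome[chrom2])),
                    "+" if rng.random() < 0.5 else "-",
                    name=f"background_{k}",
                )
            )
    profile.svs.extend(new_svs)
    return new_svs


def _ecdna_intercept(cfg: SimulationConfig) -> float:
    """Logistic intercept giving the configured marginal ecDNA prevalence."""
    beta = math.log(cfg.effect_or_wgd_ecdna)
    wf = cfg.wgd_fraction
    target = cfg.ecdna_fraction

    def marginal(b0: float) -> float:
        return (1 - wf) * expit(b0) + wf * expit(b0 + beta) - target

    if target <= 0.0:
        return -math.inf
    if target >= 1.0:
        return math.inf
    return brentq(marginal, -30.0, 30.0)


ANCESTRIES = ("EUR", "EAS", "AFR", "AMR")
HISTOLOGIES = ("LUAD", "LUSC", "carcinoid", "other")
STAGES = ("I", "II", "III", "IV")

BASELINE_HAZARD = math.log(2) / 36.0  # median overall survival 36 months


def simulate_clinical(
    truths: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw clinical covariates, ecDNA status and survival for a cohort.

    ``truths`` needs ``sample_id``, ``purity`` and ``is_wgd`` columns;
    ``has_ecdna``/``has_bfb``/``has_linear_amp``/``has_chromothripsis``
    are drawn here when absent. ecDNA status follows a logistic model
    whose WGD coefficient is ``log(effect_or_wgd_ecdna)`` and whose
    intercept is calibrated to the configured marginal prevalence.
    Survival times are exponential with hazard multiplied by
    ``effect_hr_ecdna`` for ecDNA-positive samples; censoring is an
    independent exponential time tuned to the configured censored
    fraction.
    """
    df = truths.copy().reset_index(drop=True)
    n = len(df)
    if "has_ecdna" not in df:
        b0 = _ecdna_intercept(cfg)
        logit = b0 + math.log(cfg.effect_or_wgd_ecdna) * df["is_wgd"].astype(float)
        df["has_ecdna"] = rng.random(n) < expit(logit)
    if "has_bfb" not in df:
        df["has_bfb"] = rng.random(n) < cfg.bfb_fraction
    if "has_linear_amp" not in df:
        df["has_linear_amp"] = rng.random(n) < cfg.linear_amp_fraction
    if "has_chromothripsis" not in df:
        df["has_chromothripsis"] = rng.random(n) < cfg.chromothripsis_fraction

    df["age"] = np.clip(np.round(rng.normal(65, 10, size=n)), 30, 90).astype(int)
    df["sex"] = rng.choice(["F", "M"], size=n)
    df["ancestry"] = rng.choice(ANCESTRIES, size=n, p=[0.45, 0.40, 0.08, 0.07])
    df["histology"] = rng.choice(HISTOLOGIES, size=n, p=[0.84, 0.06, 0.05, 0.05])
    df["stage"] = rng.choice(STAGES, size=n, p=[0.40, 0.20, 0.25, 0.15])
    df["smoking"] = rng.choice(["never", "smoker"], size=n, p=[0.7, 0.3])

    df["amp_class"] = np.where(
        df["has_ecdna"],
        "ecdna",
        np.where(df["has_bfb"] | df["has_linear_amp"], "other_focal", "none"),
    )

    hazard = BASELINE_HAZARD * np.where(df["has_ecdna"], cfg.effect_hr_ecdna, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        rate_c = BASELINE_HAZARD * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    df["time"] = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    df["event"] = (t_event <= t_cens).astype(int)
    return df


@dataclass
class Cohort:
    cfg: SimulationConfig
    clinical: pd.DataFrame
    profiles: list[SampleProfile]


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Full cohort: clinical labels first, genomes realising them second."""
    ss = np.random.SeedSequence(cfg.rng_seed)
    children = ss.spawn(cfg.n_samples + 1)
    rng0 = np.random.default_rng(children[0])

    base = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(cfg.n_samples)],
            "purity": rng0.uniform(*cfg.purity_range, size=cfg.n_samples),
            "is_wgd": rng0.random(cfg.n_samples) < cfg.wgd_fraction,
        }
    )
    clinical = simulate_clinical(base, cfg, rng0)

    profiles: list[SampleProfile] = []
    for i, row in clinical.iterrows():
        rng = np.random.default_rng(children[i + 1])
        profile = simulate_segment_profile(
            cfg, i, rng, purity=float(row["purity"]), wgd=bool(row["is_wgd"])
        )
        chroms = [c for c, _ in cfg.genome]
        picks = rng.choice(len(chroms), size=4, replace=False)
        used: set[str] = set()

        def _locus(chrom: str, length: int) -> tuple[str, int, int]:
            clen = cfg.genome_dict[chrom]
            length = min(length, clen)
            start = int(rng.integers(0, clen - length + 1))
            return (chrom, start, start + length)

        if row["has_ecdna"]:
            chrom = chroms[int(picks[0])]
            inject_focal_amplicon(
                profile, _locus(chrom, cfg.amplicon_len), cfg.amplicon_cn,
                "cyclic", rng,
            )
            used.add(chrom)
        if row["has_bfb"]:
            chrom = chroms[int(picks[1])]
            inject_focal_amplicon(
                profile, _locus(chrom, cfg.amplicon_len), cfg.bfb_cn,
                "foldback", rng,
            )
            used.add(chrom)
        if row["has_linear_amp"]:
            chrom = chroms[int(picks[2])]
            inject_focal_amplicon(
                profile, _locus(chrom, cfg.amplicon_len), cfg.linear_cn,
                "linear", rng,
            )
            used.add(chrom)
        if row["has_chromothripsis"]:
            chrom = chroms[int(picks[3])]
            inject_chromothripsis(
                profile, chrom, cfg.chromothripsis_n_sv, rng,
                n_tra=cfg.chromothripsis_n_tra,
            )
            used.add(chrom)
        if cfg.n_background_sv:
            inject_background_svs(profile, cfg.n_background_sv, rng,
                                  exclude_chroms=used)
        profiles.append(profile)
    return Cohort(cfg=cfg, clinical=clinical, profiles=profiles)


def simulate_telomere_readgroups(
    rng: np.random.Generator,
    n_groups: int = 4,
    mean_tl_frac: float = 0.01,
    reads_per_group: int = 50_000,
):
    """Read groups with binomially sampled telomeric-read counts."""
    from .types import ReadGroupTelomere

    groups = []
    for g in range(n_groups):
        n_reads = int(rng.integers(reads_per_group // 2, reads_per_group * 2))
        frac = mean_tl_frac * float(rng.uniform(0.5, 1.5))
        n_tel = int(rng.binomial(n_reads, frac))
        groups.append(
            ReadGroupTelomere(group_id=f"rg{g}", n_reads=n_reads, n_telomeric=n_tel)
        )
    return groups
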