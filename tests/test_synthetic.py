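import math

import numpy as np
import pytest

from circlescan import copy_number as cn
from circlescan.io import write_cohort
from circlescan.synthetic import (
    SimulationConfig,
    inject_chromothripsis,
    inject_focal_amplicon,
    simulate_clinical,
    simulate_cohort,
    simulate_segment_profile,
)


def _profile(purity=0.5, wgd=False, noise=0.0, seed=0):
    cfg = SimulationConfig(logr_noise_sd=noise, rng_seed=seed)
    rng = np.random.default_rng(seed)
    return cfg, rng, simulate_segment_profile(cfg, 0, rng, purity=purity, wgd=wgd)


class TestSegmentProfile:
    def test_tiles_each_chromosome_without_gaps(self):
        cfg, _, profile = _profile()
        by_chrom = {}
        for s in profile.segments:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, length in cfg.genome:
            segs = sorted(by_chrom[chrom], key=lambda s: s.start)
            assert segs[0].start == 0 and segs[-1].end == length
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end == b.start

    @pytest.mark.parametrize("purity", [0.1, 0.37, 0.8, 1.0])
    def test_zero_noise_roundtrip_recovers_true_tcn(self, purity):
        _, _, profile = _profile(purity=purity)
        segs = profile.to_cn_segments()
        cn.annotate_segments(segs, profile.model)
        for est, true in zip(segs, profile.segments):
            assert est.tcn == pytest.approx(true.tcn, abs=1e-12)

    def test_pure_diploid_profile_has_zero_logr(self):
        cfg = SimulationConfig(logr_noise_sd=0.0, rng_seed=1)
        rng = np.random.default_rng(1)
        profile = simulate_segment_profile(cfg, 0, rng, purity=1.0, wgd=False)
        # force uniform diploid and re-emit
        for s in profile.segments:
            s.tcn, s.major, s.minor = 2.0, 1, 1
        object.__setattr__(profile.model, "ploidy", 2.0)
        profile.recompute_logr()
        assert all(s.logr == pytest.approx(0.0) for s in profile.segments)

    def test_wgd_doubles_baseline_major_cn(self):
        _, _, diploid = _profile(wgd=False)
        _, _, doubled = _profile(wgd=True)
        assert max(s.major for s in diploid.segments) <= 2
        # baseline (non-aberrant) WGD segments sit at major=2, minor=2
        assert any(s.major == 2 and s.minor == 2 for s in doubled.segments)
        assert doubled.model.ploidy > diploid.model.ploidy

    def test_ploidy_is_length_weighted_mean_tcn(self):
        _, _, profile = _profile(wgd=True)
        total = sum(s.length for s in profile.segments)
        expect = sum(s.length * s.tcn for s in profile.segments) / total
        assert profile.model.ploidy == pytest.approx(expect)

    def test_rejects_bad_purity(self):
        cfg = SimulationConfig(rng_seed=0)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_segment_profile(cfg, 0, rng, purity=0.0)
        with pytest.raises(ValueError):
            simulate_segment_profile(cfg, 0, rng, purity=1.5)


class TestFocalAmplicon:
    def test_cyclic_adds_one_cycle_closing_junction(self):
        _, rng, profile = _profile()
        svs = inject_focal_amplicon(profile, ("chr1", 2_000_000, 3_000_000), 20,
                                    "cyclic", rng)
        assert len(svs) == 1
        sv = svs[0]
        assert (sv.pos1, sv.pos2) == (2_000_000, 3_000_000)
        assert (sv.strand1, sv.strand2) == ("-", "+") and sv.svtype == "DUP"

    def test_linear_adds_no_sv(self):
        _, rng, profile = _profile()
        assert inject_focal_amplicon(
            profile, ("chr2", 0, 1_000_000), 8, "linear", rng
        ) == []
        assert profile.svs == []

    def test_foldback_adds_inverted_breakends_at_one_boundary(self):
        _, rng, profile = _profile()
        svs = inject_focal_amplicon(profile, ("chr3", 4_000_000, 5_000_000), 12,
                                    "foldback", rng)
        assert len(svs) >= 2
        assert all(v.svtype in ("h2hINV", "t2tINV") for v in svs)
        assert all(v.is_foldback() for v in svs)

    def test_emitted_logr_matches_forward_model(self):
        # rho=0.15, psi=2 (forced), cn=10 -> logR = log2(1.6)
        _, rng, profile = _profile(purity=0.15)
        object.__setattr__(profile.model, "ploidy", 2.0)
        inject_focal_amplicon(profile, ("chr4", 1_000_000, 2_000_000), 10,
                              "linear", rng)
        amp_segs = [
            s for s in profile.segments
            if s.chrom == "chr4" and 1_000_000 <= s.start < 2_000_000
        ]
        assert amp_segs
        for s in amp_segs:
            assert s.logr == pytest.approx(math.log2(1.6), abs=1e-12)

    def test_locus_outside_genome_rejected(self):
        _, rng, profile = _profile()
        with pytest.raises(ValueError):
            inject_focal_amplicon(profile, ("chrX", 0, 1000), 20, "cyclic", rng)
        with pytest.raises(ValueError):
            inject_focal_amplicon(profile, ("chr1", 0, 99_000_000), 20, "cyclic", rng)

    def test_cn_not_above_baseline_rejected(self):
        _, rng, profile = _profile(wgd=True)
        with pytest.raises(ValueError):
            inject_focal_amplicon(profile, ("chr1", 0, 1_000_000), 3, "cyclic", rng)


class TestChromothripsisInjection:
    def test_segments_oscillate_between_two_states(self):
        _, rng, profile = _profile()
        inject_chromothripsis(profile, "chr5", 10, rng)
        chrom, start, end = profile.truth.chromothripsis_regions[0]
        window = [
            s for s in profile.segments
            if s.chrom == chrom and s.start >= start and s.end <= end
        ]
        states = [s.tcn for s in window]
        assert len(set(states)) == 2
        switches = sum(a != b for a, b in zip(states[:-1], states[1:]))
        assert switches >= 10 - 1

    def test_sv_count_and_confinement(self):
        _, rng, profile = _profile()
        svs = inject_chromothripsis(profile, "chr6", 10, rng, n_tra=4)
        intra = [v for v in svs if v.is_intrachromosomal]
        tra = [v for v in svs if v.svtype == "TRA"]
        assert len(intra) == 10 and len(tra) == 4
        chrom, start, end = profile.truth.chromothripsis_regions[0]
        assert all(start <= v.pos1 and v.pos2 <= end for v in intra)

    def test_join_types_uniform_over_many_draws(self):
        _, rng, profile = _profile()
        svs = inject_chromothripsis(profile, "chr7", 10_000, rng)
        counts = {}
        for v in svs:
            counts[v.svtype] = counts.get(v.svtype, 0) + 1
        se = math.sqrt(10_000 * 0.25 * 0.75)
        for t in ("DUP", "DEL", "h2hINV", "t2tINV"):
            assert abs(counts[t] - 2500) <= 3 * se

    def test_absent_chromosome_rejected(self):
        _, rng, profile = _profile()
        with pytest.raises(ValueError):
            inject_chromothripsis(profile, "chrZ", 10, rng)


class TestClinical:
    def _base(self, n, rng, wgd_fraction):
        return {
            "sample_id": [f"S{i}" for i in range(n)],
            "purity": rng.uniform(0.2, 0.95, n),
            "is_wgd": rng.random(n) < wgd_fraction,
        }

    def test_null_wgd_effect_gives_or_near_one(self):
        import pandas as pd

        cfg = SimulationConfig(effect_or_wgd_ecdna=1.0, rng_seed=0)
        rng = np.random.default_rng(0)
        clin = simulate_clinical(
            pd.DataFrame(self._base(8000, rng, cfg.wgd_fraction)), cfg, rng
        )
        tab = pd.crosstab(clin["is_wgd"], clin["has_ecdna"])
        odds = (tab.loc[True, True] * tab.loc[False, False]) / (
            tab.loc[True, False] * tab.loc[False, True]
        )
        assert 0.8 < odds < 1.25

    def test_marginal_prevalence_matches_config(self):
        import pandas as pd

        cfg = SimulationConfig(rng_seed=0)
        rng = np.random.default_rng(1)
        clin = simulate_clinical(
            pd.DataFrame(self._base(20000, rng, cfg.wgd_fraction)), cfg, rng
        )
        assert clin["has_ecdna"].mean() == pytest.approx(cfg.ecdna_fraction, abs=0.02)

    def test_censoring_rate_respected_at_baseline_hazard(self):
        import pandas as pd

        cfg = SimulationConfig(censoring_rate=0.3, rng_seed=0)
        rng = np.random.default_rng(2)
        clin = simulate_clinical(
            pd.DataFrame(self._base(10000, rng, cfg.wgd_fraction)), cfg, rng
        )
        # the configured rate applies to baseline-hazard (ecDNA-negative)
        # samples; higher-hazard samples are censored less often
        baseline = clin[~clin["has_ecdna"]]
        assert (1 - baseline["event"].mean()) == pytest.approx(0.3, abs=0.03)


class TestCohort:
    def test_identical_seed_gives_identical_tables(self, tmp_path):
        cfg = SimulationConfig(n_samples=6, rng_seed=7)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.clinical.to_csv() == b.clinical.to_csv()
        for pa, pb in zip(a.profiles, b.profiles):
            assert pa.segment_frame().to_csv() == pb.segment_frame().to_csv()
            assert pa.sv_frame().to_csv() == pb.sv_frame().to_csv()
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        write_cohort(a, out_a)
        write_cohort(b, out_b)
        for fa in sorted(out_a.rglob("*")):
            if fa.is_file():
                fb = out_b / fa.relative_to(out_a)
                assert fa.read_bytes() == fb.read_bytes()

    def test_label_soundness(self, noiseless_cohort):
        for profile in noiseless_cohort.profiles:
            junctions = [v for v in profile.svs if v.name.startswith("ecdna_junction")]
            if profile.truth.has_ecdna:
                assert len(junctions) >= 1
            else:
                assert junctions == []

    def test_injected_loci_inside_genome(self, noiseless_cohort):
        genome = noiseless_cohort.cfg.genome_dict
        for profile in noiseless_cohort.profiles:
            for rec in profile.truth.amplicons:
                assert 0 <= rec["start"] < rec["end"] <= genome[rec["chrom"]]
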