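"""Segmentation, significance testing, filtering and genotyping."""

import numpy as np
import pytest
from scipy import stats

from rdcnv import (
    ReadDepthProfile,
    SimulationConfig,
    apply_filters,
    call_cnvs,
    genotype_region,
    genotype_windows,
    segment_signal,
    simulate_genome,
    simulate_read_depth,
)
from rdcnv import test_segments as test_segments  # noqa: F401

# pytest would otherwise collect the imported operation as a test
score_segments = test_segments
del test_segments
from rdcnv.calling import CNVCall
from rdcnv.simulate import TruthEvent, TruthSet

from conftest import flat_genome


def profile_from(vals, genome, sample="s"):
    return ReadDepthProfile.from_counts(sample, genome, {"chr1": np.asarray(vals, float)})


def exhaustive_single_breakpoint(x):
    """Oracle: best single change point by least squares; None if flat."""
    best, best_sse = None, ((x - x.mean()) ** 2).sum()
    for b in range(1, len(x)):
        l, r = x[:b], x[b:]
        sse = ((l - l.mean()) ** 2).sum() + ((r - r.mean()) ** 2).sum()
        if sse < best_sse - 1e-9:
            best, best_sse = b, sse
    return best


class TestSegmentation:
    def test_constant_signal_single_segment(self):
        genome = flat_genome(length=20_000)
        prof = profile_from(np.full(200, 10.0), genome)
        segs = segment_signal(prof, genome, "chr1")
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (1, 20_000)

    def test_noise_free_step_matches_ls_oracle(self):
        genome = flat_genome(length=20_000)
        x = np.concatenate([np.full(100, 500.0), np.full(100, 1000.0)])
        prof = profile_from(x, genome)
        segs = segment_signal(prof, genome, "chr1")
        assert len(segs) == 2
        assert segs[0].end == 100 * 100  # breakpoint after bin 100
        assert exhaustive_single_breakpoint(x) == 100

    def test_poisson_cn4_event_boundaries_within_2_bins(self):
        genome = flat_genome(length=50_000)
        rng = np.random.default_rng(12)
        x = rng.poisson(10, 500).astype(float)
        x[200:250] = rng.poisson(20, 50)
        prof = profile_from(x, genome)
        segs = segment_signal(prof, genome, "chr1")
        elevated = [s for s in segs if s.mean_rd > 1.5 * prof.mean]
        assert elevated
        assert abs((min(s.start for s in elevated) - 1) // 100 - 200) <= 2
        assert abs((max(s.end for s in elevated) - 1) // 100 + 1 - 250) <= 2

    def test_partition_covers_non_gap_bins_exactly_once(self, small_cohort):
        cfg, genome, truth, profiles = small_cohort
        segs = segment_signal(profiles["S02"], genome, "chr1")
        mask = genome.gap_mask("chr1")
        covered = np.zeros(len(mask), dtype=int)
        for s in segs:
            covered[(s.start - 1) // 100 : (s.end - 1) // 100 + 1] += 1
        assert (covered[~mask] == 1).all()
        assert (covered[mask] == 0).all()

    def test_short_chromosome_single_segment_with_warning(self):
        genome = flat_genome(length=200)
        prof = profile_from([5.0, 5.0], genome)
        with pytest.warns(UserWarning, match="bandwidth"):
            segs = segment_signal(prof, genome, "chr1")
        assert len(segs) == 1


class TestSignificance:
    def test_segment_at_global_mean_is_not_candidate(self):
        genome = flat_genome(length=20_000)
        prof = profile_from(np.full(200, 10.0), genome)
        segs = segment_signal(prof, genome, "chr1")
        assert score_segments(segs, prof, genome) == []

    def test_doubled_segment_gets_cn4_and_tiny_p(self):
        genome = flat_genome(length=100_000)
        rng = np.random.default_rng(1)
        x = 10.0 + 0.01 * rng.standard_normal(1_000)
        x[500:550] = 20.0 + 0.01 * rng.standard_normal(50)
        prof = profile_from(x, genome)
        segs = segment_signal(prof, genome, "chr1")
        cands = score_segments(segs, prof, genome)
        assert len(cands) == 1
        assert cands[0].cn == pytest.approx(4.0, abs=0.01)
        assert cands[0].p_value < 1e-10
        assert cands[0].type == "duplication"

    def test_p_values_match_hand_rolled_t_formula(self, small_cohort):
        cfg, genome, truth, profiles = small_cohort
        prof = profiles["S01"]
        segs = segment_signal(prof, genome, "chr1")
        cands = score_segments(segs, prof, genome)
        assert cands
        mask = genome.gap_mask("chr1")
        for c in cands:
            bins = prof.corrected["chr1"][(c.start - 1) // 100 : (c.end - 1) // 100 + 1]
            bins = bins[~mask[(c.start - 1) // 100 : (c.end - 1) // 100 + 1]]
            if len(bins) < 2 or bins.std(ddof=1) < 1e-12:
                continue
            t = (bins.mean() - prof.mean) / (bins.std(ddof=1) / np.sqrt(len(bins)))
            p = 2 * stats.t.sf(abs(t), len(bins) - 1)
            assert c.p_value == pytest.approx(p, rel=1e-6)

    def test_single_bin_deviant_flagged_and_rejected_with_reason(self):
        from rdcnv.calling import Segment

        genome = flat_genome(length=1_000, bin_size=100)
        x = np.full(10, 10.0)
        x[4] = 30.0
        prof = profile_from(x, genome)
        segs = [
            Segment("chr1", 1, 400, 10.0, 4),
            Segment("chr1", 401, 500, 30.0, 1),
            Segment("chr1", 501, 1_000, 10.0, 5),
        ]
        cands = score_segments(segs, prof, genome)
        single = [c for c in cands if "single-bin" in c.flags]
        assert len(single) == 1 and np.isnan(single[0].p_value)
        kept, log = apply_filters(cands, genome)
        assert kept == []
        assert "single-bin" in log["reason"][log.start == 401].iloc[0]


def mk_call(start, end, p=1e-6, q0=0.0, cn=4.0, kind="duplication", sample="s", chrom="chr1"):
    return CNVCall(sample, chrom, start, end, kind, cn, p, q0)


class TestFilters:
    @pytest.mark.parametrize(
        "call,reason",
        [
            (mk_call(1_001, 1_900, p=1e-9), "size"),  # 900 bp despite tiny p
            (mk_call(1_001, 3_000, q0=0.6), "q0"),  # >50% ambiguous reads
            (mk_call(1_001, 3_000, p=0.5), "pvalue"),
        ],
    )
    def test_rejection_reasons(self, call, reason):
        genome = flat_genome(length=100_000)
        kept, log = apply_filters([call], genome)
        assert kept == []
        assert reason in log["reason"].iloc[0]

    def test_all_gates_pass(self):
        genome = flat_genome(length=100_000)
        kept, log = apply_filters([mk_call(1_001, 2_101)], genome)  # 1.1 kb
        assert len(kept) == 1 and log.empty

    def test_gap_overlap_excluded_unless_raw_mode(self):
        genome = flat_genome(length=100_000, gaps=[(5_001, 6_000)])
        call = mk_call(4_001, 7_000)
        kept, log = apply_filters([call], genome)
        assert kept == [] and "gap" in log["reason"].iloc[0]
        kept_raw, _ = apply_filters([call], genome, keep_gap_calls=True)
        assert len(kept_raw) == 1 and "gap-overlap" in kept_raw[0].flags

    def test_same_type_calls_separated_only_by_gap_merge(self):
        genome = flat_genome(length=100_000, gaps=[(10_001, 12_000)])
        a = mk_call(5_001, 10_000)
        b = mk_call(12_001, 15_000)
        kept, _ = apply_filters([a, b], genome)
        assert len(kept) == 1
        assert (kept[0].start, kept[0].end) == (5_001, 15_000)
        assert "gap-merged" in kept[0].flags

    def test_filter_monotonicity(self, small_cohort):
        """Lowering p_max or raising min_len never increases survivors."""
        cfg, genome, truth, profiles = small_cohort
        prof = profiles["S03"]
        segs = segment_signal(prof, genome, "chr1")
        cands = score_segments(segs, prof, genome)
        base, _ = apply_filters(cands, genome, p_max=0.01, min_len=1_000)
        stricter_p, _ = apply_filters(cands, genome, p_max=1e-4, min_len=1_000)
        stricter_len, _ = apply_filters(cands, genome, p_max=0.01, min_len=5_000)
        assert len(stricter_p) <= len(base)
        assert len(stricter_len) <= len(base)


class TestGenotyping:
    def test_neutral_autosome_genotypes_at_two(self, clean_cohort):
        cfg, genome, truth, profiles = clean_cohort
        prof = profiles["S01"]
        region = None
        mask = genome.gap_mask("chr1")
        for s in range(0, len(mask) - 100, 100):
            window = (s * 100 + 1, s * 100 + 10_000)
            if mask[s : s + 100].any():
                continue
            if not any(
                e.start <= window[1] and e.end >= window[0] for e in truth.events_for("S01")
            ):
                region = ("chr1",) + window
                break
        assert genotype_region(prof, region, genome) == pytest.approx(2.0, abs=1e-6)

    def test_neutral_chrz_female_genotypes_at_one(self, z_cohort):
        cfg, genome, truth, profiles = z_cohort
        prof = profiles["S01"]
        evs = truth.events_for("S01", "chrZ")
        start = 1
        while any(e.start <= start + 9_999 and e.end >= start for e in evs):
            start += 10_000
        cn = genotype_region(prof, ("chrZ", start, start + 9_999), genome)
        assert cn == pytest.approx(1.0, abs=0.02)

    def test_high_copy_locus_estimate_within_03(self):
        # a CN 6.4 locus, like a heavily duplicated gene in one bird
        cfg = SimulationConfig(
            seed=21,
            n_samples=1,
            chromosomes=(("chr1", 2_000_000),),
            events_per_sample=0,
            gap_fraction=0.0,
        )
        genome, truth = simulate_genome(cfg)
        truth = TruthSet(
            [TruthEvent("S01", "chr1", 1_000_001, 1_020_000, 6.4)], truth.depth_multiplier
        )
        from rdcnv import gc_correct

        prof = gc_correct(simulate_read_depth(genome, truth, "S01", cfg), genome)
        cn = genotype_region(prof, ("chr1", 1_000_001, 1_020_000), genome)
        assert cn == pytest.approx(6.4, abs=0.3)

    def test_wholly_gap_region_is_nan(self):
        genome = flat_genome(length=10_000, gaps=[(2_001, 3_000)])
        prof = profile_from(np.full(100, 10.0), genome)
        assert np.isnan(genotype_region(prof, ("chr1", 2_001, 3_000), genome))


class TestGenotypeWindows:
    def test_constant_signal_all_windows_cn2(self):
        genome = flat_genome(length=100_000)
        prof = profile_from(np.full(1_000, 10.0), genome)
        df, mean, stdev = genotype_windows(prof, genome, window=5_000)
        assert len(df) == 20
        assert np.allclose(df["cn"], 2.0)
        assert mean == pytest.approx(2.0) and stdev == pytest.approx(0.0)

    def test_window_overlapping_exclusion_by_1bp_dropped(self):
        genome = flat_genome(length=100_000)
        prof = profile_from(np.full(1_000, 10.0), genome)
        # a 1 bp exclusion at position 5,000 touches only the first window
        df, _, _ = genotype_windows(prof, genome, window=5_000, exclude=[("chr1", 5_000, 5_000)])
        assert len(df) == 19 and 1 not in set(df["start"])
        # at 5,001 it touches only the second window
        df2, _, _ = genotype_windows(prof, genome, window=5_000, exclude=[("chr1", 5_001, 5_001)])
        assert len(df2) == 19 and 5_001 not in set(df2["start"])

    def test_everything_excluded_gives_empty_flagged_result(self):
        genome = flat_genome(length=10_000)
        prof = profile_from(np.full(100, 10.0), genome)
        df, mean, stdev = genotype_windows(prof, genome, window=5_000, exclude=[("chr1", 1, 10_000)])
        assert df.empty and np.isnan(mean)


def test_noise_free_pipeline_emits_exactly_the_embedded_events(clean_cohort):
    cfg, genome, truth, profiles = clean_cohort
    for sample, prof in profiles.items():
        calls, _ = call_cnvs(prof, genome)
        expected = sorted(
            (e.start, e.end) for e in truth.events_for(sample) if e.length > 1_000
        )
        got = sorted((c.start, c.end) for c in calls)
        assert got == expected
        for c in calls:
            ev = [e for e in truth.events_for(sample) if (e.start, e.end) == (c.start, c.end)][0]
            assert c.cn == pytest.approx(ev.cn, abs=1e-6)
            assert (c.type == "duplication") == (ev.cn > genome.ploidy[c.chrom])
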