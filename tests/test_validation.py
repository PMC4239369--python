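"""Digital aCGH, qPCR copy-number estimation and neutral-region QC."""

import math

import numpy as np
import pandas as pd
import pytest

from rdcnv import (
    call_cnvs,
    confirmation_rates,
    correlate_validation,
    digital_acgh,
    neutral_qc_report,
    probe_segment_mean,
    qpcr_copy_number,
    simulate_acgh,
    simulate_qpcr,
    split_pairwise_segments,
)
from rdcnv.calling import CNVCall
from rdcnv.intervals import merge_intervals
from rdcnv.validation import qpcr_status


def call(sample, start, end, kind="duplication", chrom="chr1"):
    return CNVCall(sample, chrom, start, end, kind, 4.0, 1e-6, 0.0)


class TestSplitPairwise:
    def test_breakpoint_partition_of_overlapping_pair(self):
        a = [call("A", 100_000, 300_000)]
        b = [call("B", 200_000, 400_000)]
        segs = split_pairwise_segments(a, b, min_len=0)
        got = [(s.start, s.end, s.origin) for s in segs.segments]
        assert got == [
            (100_000, 199_999, "test"),
            (200_000, 300_000, "both"),
            (300_001, 400_000, "ref"),
        ]

    def test_unique_call_kept_whole(self):
        a = [call("A", 100_000, 105_000)]
        segs = split_pairwise_segments(a, [], min_len=1_000)
        assert [(s.start, s.end, s.origin) for s in segs.segments] == [
            (100_000, 105_000, "test_unique")
        ]

    def test_short_segments_discarded(self):
        a = [call("A", 1_000, 2_500)]
        b = [call("B", 1_000, 3_000)]
        segs = split_pairwise_segments(a, b, min_len=1_000)
        # pieces: [1000,2500] (1501 bp, kept) and [2501,3000] (500 bp, dropped)
        assert [(s.start, s.end) for s in segs.segments] == [(1_000, 2_500)]

    def test_random_pairs_match_sweep_oracle_and_conserve_length(self):
        rng = np.random.default_rng(5)
        a = []
        pos = 1
        for ln in rng.integers(2_000, 30_000, 25):
            a.append(call("A", pos, pos + int(ln)))
            pos += int(ln) + int(rng.integers(1_000, 20_000))
        b = []
        pos = 4_000
        for ln in rng.integers(2_000, 30_000, 25):
            b.append(call("B", pos, pos + int(ln)))
            pos += int(ln) + int(rng.integers(1_000, 20_000))
        segs = split_pairwise_segments(a, b, min_len=0)
        # conservation: subsegment lengths sum to the union of all calls
        union = merge_intervals([c.interval for c in a + b])
        union_len = sum(e - s + 1 for s, e in union)
        assert sum(s.length for s in segs.segments) == union_len
        # oracle: per-bp coverage flags from an event-point sweep
        for seg in segs.segments:
            mid = (seg.start + seg.end) // 2
            in_a = any(c.start <= mid <= c.end for c in a)
            in_b = any(c.start <= mid <= c.end for c in b)
            expected = {
                (True, True): "both",
                (True, False): ("test", "test_unique"),
                (False, True): ("ref", "ref_unique"),
            }[(in_a, in_b)]
            assert seg.origin in expected
        # disjointness
        ordered = sorted(segs.segments, key=lambda s: s.start)
        assert all(x.end < y.start for x, y in zip(ordered, ordered[1:]))


class TestDigitalAcgh:
    def test_noise_free_digital_values_equal_true_log2_ratios(self, clean_cohort):
        cfg, genome, truth, profiles = clean_cohort
        t, r = "S01", "S02"
        calls = {s: call_cnvs(profiles[s], genome)[0] for s in (t, r)}
        segs = split_pairwise_segments(calls[t], calls[r])
        df = digital_acgh(profiles[t], profiles[r], segs, genome)
        assert len(df)
        for _, row in df.iterrows():
            mid = (row.start + row.end) // 2
            cn_t = max(truth.cn_at(t, "chr1", mid, genome), 0.5)
            cn_r = max(truth.cn_at(r, "chr1", mid, genome), 0.5)
            assert row.log2ratio == pytest.approx(math.log2(cn_t / cn_r), abs=1e-6)

    def test_antisymmetric_under_pair_swap(self, clean_cohort):
        cfg, genome, truth, profiles = clean_cohort
        t, r = "S01", "S03"
        calls = {s: call_cnvs(profiles[s], genome)[0] for s in (t, r)}
        segs = split_pairwise_segments(calls[t], calls[r])
        fwd = digital_acgh(profiles[t], profiles[r], segs, genome)
        rev = digital_acgh(profiles[r], profiles[t], segs, genome)
        np.testing.assert_allclose(fwd.log2ratio, -rev.log2ratio, atol=1e-9)


class TestProbeSegmentMean:
    def test_trivial_means(self):
        probes = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [10, 20, 99], "log2ratio": [0.9, 1.1, 0.3]}
        )
        assert probe_segment_mean(probes, ("chr1", 5, 25)) == pytest.approx(1.0)
        assert probe_segment_mean(probes, ("chr1", 90, 100)) == pytest.approx(0.3)
        assert np.isnan(probe_segment_mean(probes, ("chr1", 200, 300)))

    def test_random_layout_matches_linear_scan(self):
        rng = np.random.default_rng(6)
        probes = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": rng.integers(1, 100_000, 500),
                "log2ratio": rng.normal(0, 1, 500),
            }
        )
        seg = ("chr1", 20_000, 40_000)
        expected = np.mean(
            [v for p, v in zip(probes.pos, probes.log2ratio) if 20_000 <= p <= 40_000]
        )
        assert probe_segment_mean(probes, seg) == pytest.approx(expected)


class TestCorrelate:
    def test_identity_pairs(self):
        x = [0.1, 0.5, -0.4, 1.2, 0.0]
        out = correlate_validation(x, x)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0)

    def test_anticorrelated_pairs(self):
        x = np.array([0.1, 0.5, -0.4, 1.2])
        assert correlate_validation(x, -x)["r"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        out = correlate_validation([1.0, 1.0, 1.0], [0.2, 0.4, 0.9])
        assert out["degenerate"] and np.isnan(out["r"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_validation([1.0, 2.0], [1.0, 2.0])

    def test_r_decreases_with_probe_noise(self, clean_cohort):
        """Attenuation: more probe noise, lower digital-vs-probe correlation."""
        cfg, genome, truth, profiles = clean_cohort
        import dataclasses

        t, r = "S01", "S02"
        calls = {s: call_cnvs(profiles[s], genome)[0] for s in (t, r)}
        segs = split_pairwise_segments(calls[t], calls[r])
        digital = digital_acgh(profiles[t], profiles[r], segs, genome)
        rs = []
        for sd in (0.05, 0.4, 1.5):
            cfg_n = dataclasses.replace(cfg, probe_noise_sd=sd)
            probes = simulate_acgh(truth, truth, genome, cfg_n, t, r, seed=123)
            exp = [probe_segment_mean(probes, (row.chrom, row.start, row.end))
                   for _, row in digital.iterrows()]
            rs.append(correlate_validation(digital.log2ratio, exp)["r"])
        assert rs[0] > rs[1] > rs[2]


class TestQpcr:
    def _table(self, ddct_by_sample, replicates=3):
        rows = []
        for sample, ddct in ddct_by_sample.items():
            for rep in range(1, replicates + 1):
                rows.append((sample, "R1", rep, 24.0 + ddct, 20.0))
        return pd.DataFrame(
            rows, columns=["sample", "region", "replicate", "Ct_target", "Ct_control"]
        )

    @pytest.mark.parametrize("ddct,cn", [(0.0, 2.0), (1.0, 1.0), (-1.0, 4.0)])
    def test_ddct_to_copy_number(self, ddct, cn):
        ct = self._table({"ref": 0.0, "test": ddct})
        out = qpcr_copy_number(ct, "R1", "ref")
        assert out["test"] == pytest.approx(cn)
        assert out["ref"] == pytest.approx(2.0)

    def test_chrz_female_baseline_is_one_copy(self):
        ct = self._table({"ref": 0.0, "test": 0.0})
        out = qpcr_copy_number(ct, "R1", "ref", ploidy_ref=1)
        assert out["test"] == pytest.approx(1.0)

    def test_missing_replicates_excluded(self):
        ct = self._table({"ref": 0.0, "test": 0.0})
        ct = ct.drop(ct[(ct["sample"] == "test") & (ct.replicate > 1)].index)
        out = qpcr_copy_number(ct, "R1", "ref", expected_replicates=3)
        assert "test" not in out.index and out.attrs["excluded"] == ["test"]

    def test_round_trip_with_simulator_at_zero_noise(self, clean_cohort):
        cfg, genome, truth, profiles = clean_cohort
        ev = truth.events[0]
        mid0 = (ev.start + ev.end) // 2
        ref = next(
            s for s in truth.samples
            if truth.cn_at(s, ev.chrom, mid0, genome) == genome.ploidy[ev.chrom]
        )
        regions = {"Rev": (ev.chrom, ev.start, ev.end)}
        ct = simulate_qpcr(truth, regions, ref, genome, cfg)
        out = qpcr_copy_number(ct, "Rev", ref)
        assert out[ev.sample] == pytest.approx(max(ev.cn, 0.5), abs=1e-9)
        for s in truth.samples:
            mid = (ev.start + ev.end) // 2
            assert out[s] == pytest.approx(max(truth.cn_at(s, ev.chrom, mid, genome), 0.5))


class TestConfirmationRates:
    def test_simple_ratios(self):
        preds = {"R1": {f"s{i}": "duplication" for i in range(10)}}
        preds["R1"].update({f"n{i}": None for i in range(5)})
        qp = {"R1": {f"s{i}": (4.0 if i < 9 else 2.0) for i in range(10)}}
        qp["R1"].update({f"n{i}": 2.0 for i in range(5)})
        out = confirmation_rates(preds, qp)
        assert out["ppv_pct_mean"] == pytest.approx(90.0)
        assert out["fnr_pct_mean"] == pytest.approx(0.0)

    def test_region_without_positives_excluded_from_ppv_average(self):
        preds = {"R1": {"a": None}, "R2": {"a": "deletion"}}
        qp = {"R1": {"a": 2.0}, "R2": {"a": 1.0}}
        out = confirmation_rates(preds, qp)
        assert out["regions_without_positives"] == ["R1"]
        assert out["ppv_pct_mean"] == pytest.approx(100.0)

    def test_status_cuts(self):
        assert qpcr_status(2.6) == "gain"
        assert qpcr_status(1.4) == "loss"
        assert qpcr_status(2.0) == "normal"
        assert qpcr_status(1.6, ploidy=1) == "gain"

    def test_noise_free_cohort_ppv_100_fnr_0(self, clean_cohort):
        cfg, genome, truth, profiles = clean_cohort
        calls = {s: call_cnvs(profiles[s], genome)[0] for s in truth.samples}
        # choose a few called regions; test every sample for each
        regions, preds, qp = {}, {}, {}
        for ev in truth.events[:6]:
            if ev.length <= 1_000:
                continue
            name = f"{ev.chrom}:{ev.start}"
            regions[name] = (ev.chrom, ev.start, ev.end)
            ref = next(
                s for s in truth.samples
                if truth.cn_at(s, ev.chrom, (ev.start + ev.end) // 2, genome)
                == genome.ploidy[ev.chrom]
            )
            ct = simulate_qpcr(truth, {name: regions[name]}, ref, genome, cfg)
            qp[name] = qpcr_copy_number(ct, name, ref).to_dict()
            preds[name] = {}
            mid = (ev.start + ev.end) // 2  # where the primers sit
            for s in truth.samples:
                hit = [
                    c for c in calls[s] if c.chrom == ev.chrom and c.start <= mid <= c.end
                ]
                preds[name][s] = hit[0].type if hit else None
        out = confirmation_rates(preds, qp)
        assert out["ppv_pct_mean"] == pytest.approx(100.0)
        assert out["fnr_pct_mean"] == pytest.approx(0.0)


class TestNeutralQc:
    def test_noise_free_diploid_sample_is_2_pm_0(self, clean_cohort):
        cfg, genome, truth, profiles = clean_cohort
        calls = {s: call_cnvs(profiles[s], genome)[0] for s in truth.samples}
        report = neutral_qc_report(profiles, calls, genome)
        assert len(report) == len(truth.samples)
        for _, row in report.iterrows():
            assert row.mean_cn == pytest.approx(2.0, abs=1e-6)
            assert row.stdev_cn == pytest.approx(0.0, abs=1e-6)

    def test_sample_with_everything_excluded_absent(self, clean_cohort):
        cfg, genome, truth, profiles = clean_cohort
        calls = {s: [call(s, 1, genome.length("chr1"))] for s in truth.samples}
        report = neutral_qc_report(profiles, calls, genome)
        assert report.empty
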