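"""Validate read-depth CNV calls with digital aCGH and qPCR (ddCt).

Digital aCGH: split a (test, reference) pair's calls into disjoint
subsegments, genotype each segment in both samples and correlate
log2(CN_test/CN_ref) with simulated hybridization-probe log2 ratios.
qPCR: recover absolute copy number from triplicate Ct tables via
CN = 2^(1 - ddCt) and score the calls' positive predictive value and
false-negative rate. Neutral-region QC: CNV-free autosomal 5 kb windows
should genotype at ~2 copies.
"""

from rdcnv import (
    SimulationConfig, correlate_validation, digital_acgh, neutral_qc_report,
    probe_segment_mean, qpcr_copy_number, simulate_acgh, simulate_cohort,
    simulate_qpcr, split_pairwise_segments,
)
from rdcnv.benchmark import cohort_calls

cfg = SimulationConfig(seed=13, n_samples=4, chromosomes=(("chr1", 3_000_000),),
                       events_per_sample=10)
genome, truth, profiles = simulate_cohort(cfg)
calls = cohort_calls(profiles, genome)

test, ref = "S01", "S02"
segs = split_pairwise_segments(calls[test], calls[ref])
digital = digital_acgh(profiles[test], profiles[ref], segs, genome)
probes = simulate_acgh(truth, truth, genome, cfg, test, ref)
probe_means = [probe_segment_mean(probes, (r.chrom, r.start, r.end))
               for _, r in digital.iterrows()]
corr = correlate_validation(digital.log2ratio, probe_means)
print(f"digital aCGH vs probes ({test} vs {ref}): "
      f"r={corr['r']:.3f} over {corr['n']} segments, slope={corr['slope']:.2f}")

ev = next(e for e in truth.events if e.length > 5_000)
mid = (ev.start + ev.end) // 2
ref_s = next(s for s in truth.samples
             if truth.cn_at(s, ev.chrom, mid, genome) == genome.ploidy[ev.chrom])
region = {"R1": (ev.chrom, ev.start, ev.end)}
ct = simulate_qpcr(truth, region, ref_s, genome, cfg)
cn = qpcr_copy_number(ct, "R1", ref_s)
print(f"\nqPCR copy number at {ev.chrom}:{ev.start}-{ev.end} "
      f"(true carrier {ev.sample} has CN {ev.cn}):")
for s, v in cn.items():
    print(f"  {s}: {v:.2f}")

qc = neutral_qc_report(profiles, calls, genome)
print("\nneutral-region QC (should sit near 2.0 +- small):")
print(qc.to_string(index=False))
print(f"cohort: {qc.attrs['grand_mean']:.3f} +- {qc.attrs['grand_stdev']:.3f}")
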