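"""Merge per-sample CNV calls into CNV regions (CNVRs) and summarize them.

Calls from a 12-sample cohort that share at least 1 bp merge transitively
into CNVRs classed gain / loss / both. The summary mirrors a discovery
study's headline tables: size classes, frequency classes (how many samples
carry each region) and per-chromosome density (mean distance between CNVRs).
"""

from rdcnv import SimulationConfig, merge_to_cnvrs, simulate_cohort, summarize_cnvrs
from rdcnv.benchmark import cohort_calls

cfg = SimulationConfig(seed=2, n_samples=12, chromosomes=(("chr1", 3_000_000),),
                       events_per_sample=10)
genome, truth, profiles = simulate_cohort(cfg)
calls = cohort_calls(profiles, genome)
cnvrs = merge_to_cnvrs([c for cs in calls.values() for c in cs])

s = summarize_cnvrs(cnvrs, genome)
print(f"{s['n_cnvrs']} CNVRs covering {s['total_length_bp']/1e6:.2f} Mb "
      f"({100*s['total_length_bp']/3_000_000:.1f}% of the genome)")
print(f"lengths {s['length_min_bp']/1000:.1f}-{s['length_max_bp']/1000:.1f} kb, "
      f"mean {s['length_mean_bp']/1000:.1f} kb, median {s['length_median_bp']/1000:.1f} kb\n")
print("size classes:\n", s["size_classes"].to_string(index=False), "\n")
print("frequency classes:\n", s["frequency_classes"].to_string(index=False), "\n")
print("gain/loss/both:\n", s["classes"].to_string(index=False), "\n")
print("per chromosome:\n", s["per_chromosome"].to_string(index=False))
print(
    "\nGain regions tend to outnumber and outsize losses because the"
    "\ngenerator embeds gains slightly more often, mirroring real cohorts."
)
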