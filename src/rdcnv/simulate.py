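"""Synthetic cohort generator with known copy-number truth.

Emulates the inputs of a multi-sample whole-genome read-depth CNV study:

* a reference genome with a smooth GC landscape, assembly gaps and ambiguous
  "repeat" intervals (high zero-mapping-quality fraction),
* per-sample binned read counts at roughly 8-12x equivalent coverage with a
  unimodal GC sampling bias and embedded gains and losses (integer copy
  number, gains up to ~40 configurable),
* array-CGH probe log2 ratios for a test/reference sample pair, and
* triplicate qPCR Ct tables for chosen primer regions.

The unit of simulation is the per-bin read count; reads and alignments
themselves are never generated. All outputs are bit-for-bit reproducible from
``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import AUTOSOME_PLOIDY, GenomeModel
from .intervals import overlaps


class PlacementError(RuntimeError):
    """Raised when the requested events cannot be placed without overlap."""


@dataclasses.dataclass(frozen=True)
class TruthEvent:
    sample: str
    chrom: str
    start: int  # 1-based inclusive, bin-aligned
    end: int
    cn: int  # absolute integer copy number, != chromosome baseline

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class TruthSet:
    """Ground truth of a simulated cohort."""

    events: list[TruthEvent]
    depth_multiplier: dict[str, float]

    @property
    def samples(self) -> list[str]:
        return list(self.depth_multiplier)

    def events_for(self, sample: str, chrom: str | None = None) -> list[TruthEvent]:
        return [
            ev
            for ev in self.events
            if ev.sample == sample and (chrom is None or ev.chrom == chrom)
        ]

    def cn_at(self, sample: str, chrom: str, pos: int, genome: GenomeModel) -> int:
        """Absolute copy number of ``sample`` at a single position."""
        for ev in self.events:
            if ev.sample == sample and ev.chrom == chrom and ev.start <= pos <= ev.end:
                return ev.cn
        return genome.ploidy[chrom]


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the study design this package targets: 12 female
    samples, 100 bp bins, ~10 reads per bin (the equivalent of ~10x coverage
    with 100 bp reads) with per-sample depth spread 0.8-1.25x, Poisson
    counting noise, a quadratic GC bias peaking at GC 0.45, ~1% of the genome
    in gaps, a 2% background q0 fraction rising to 80% in repeat intervals,
    event lengths 2-50 kb and integer copy numbers drawn from {3, 4, 6}
    (gains) and {0, 1} (losses) with gains slightly more frequent than
    losses.
    """

    seed: int = 0
    n_samples: int = 12
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),)
    bin_size: int = 100
    # GC landscape: smooth field centred at gc_mean, clipped to gc_range
    gc_mean: float = 0.45
    gc_sd: float = 0.06
    gc_corr_length: int = 50_000
    gc_range: tuple[float, float] = (0.25, 0.65)
    # gaps and repeats (bin-aligned)
    gap_fraction: float = 0.01
    gap_length: tuple[int, int] = (1_000, 10_000)
    repeat_fraction: float = 0.005
    repeat_length: tuple[int, int] = (1_000, 5_000)
    # events
    events_per_sample: int = 30
    event_length: tuple[int, int] = (2_000, 50_000)
    gain_cns: tuple[int, ...] = (3, 4, 6)
    loss_cns: tuple[int, ...] = (0, 1)
    gain_prob: float = 0.55
    min_event_separation: int = 1_000  # bp between events of one sample
    # depth model
    reads_per_bin: float = 10.0
    depth_multiplier_range: tuple[float, float] = (0.8, 1.25)
    noise: str = "poisson"  # "poisson" | "none" | "nb"
    nb_dispersion: float = 0.1  # var = mu + nb_dispersion * mu^2
    gc_bias_strength: float = 8.0  # quadratic curvature; 0 = flat
    gc_bias_peak: float = 0.45
    q0_background: float = 0.02
    q0_repeat: float = 0.8
    # aCGH
    probe_spacing: int = 700
    probe_noise_sd: float = 0.2
    # qPCR
    qpcr_replicates: int = 3
    qpcr_ct_noise_sd: float = 0.1
    qpcr_efficiency: float = 2.0  # per-cycle amplification factor

    def __post_init__(self) -> None:
        for name in (
            "gap_fraction",
            "repeat_fraction",
            "probe_noise_sd",
            "qpcr_ct_noise_sd",
            "q0_background",
            "q0_repeat",
            "nb_dispersion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise not in ("poisson", "none", "nb"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.bin_size < 1 or self.probe_spacing < 1:
            raise ValueError("bin_size and probe_spacing must be positive")

    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


def gc_bias_curve(gc: np.ndarray, strength: float, peak: float) -> np.ndarray:
    """Unimodal quadratic GC bias, floored at 0.1 so no bin goes dark."""
    return np.maximum(1.0 - strength * (np.asarray(gc, float) - peak) ** 2, 0.1)


# ---------------------------------------------------------------------------
# genome + truth


def simulate_genome(config: SimulationConfig) -> tuple[GenomeModel, TruthSet]:
    """Draw a reference genome and a cohort truth set.

    Gap, repeat and event intervals are aligned to bin boundaries (the
    simulator works at bin resolution); events of one sample never overlap
    each other, gaps, or come closer than ``min_event_separation``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    bs = config.bin_size
    gc: dict[str, np.ndarray] = {}
    gaps: dict[str, list[tuple[int, int]]] = {}
    repeats: dict[str, list[tuple[int, int]]] = {}
    ploidy: dict[str, int] = {}
    for chrom, ln in config.chromosomes:
        nb = -(-ln // bs)
        gc[chrom] = _smooth_gc(nb, config, rng)
        gaps[chrom] = _place_blocks(
            ln, bs, config.gap_fraction, config.gap_length, rng, avoid=[]
        )
        repeats[chrom] = _place_blocks(
            ln, bs, config.repeat_fraction, config.repeat_length, rng, avoid=gaps[chrom]
        )
        ploidy[chrom] = 1 if chrom.lstrip("chr").upper() == "Z" else AUTOSOME_PLOIDY
    genome = GenomeModel(list(config.chromosomes), bs, gc, gaps, ploidy, repeats)

    depth_mult = {
        s: float(rng.uniform(*config.depth_multiplier_range))
        for s in config.sample_names()
    }
    events: list[TruthEvent] = []
    for sample in config.sample_names():
        events.extend(_place_events(sample, genome, config, rng))
    return genome, TruthSet(events, depth_mult)


def _smooth_gc(n_bins: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field with ~gc_corr_length correlation, clipped."""
    half = max(1, config.gc_corr_length // config.bin_size)
    raw = rng.standard_normal(n_bins + 2 * half)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / (half / 2.0)) ** 2)
    kernel /= math.sqrt((kernel**2).sum())
    smooth = np.convolve(raw, kernel, mode="same")[half : half + n_bins]
    vals = config.gc_mean + config.gc_sd * smooth
    return np.clip(vals, *config.gc_range)


def _place_blocks(
    chrom_len: int,
    bin_size: int,
    fraction: float,
    length_range: tuple[int, int],
    rng: np.random.Generator,
    avoid: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Place non-overlapping bin-aligned blocks totalling ~fraction of the chromosome."""
    target = fraction * chrom_len
    placed: list[tuple[int, int]] = []
    covered = 0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        ln = max(bin_size, (ln // bin_size) * bin_size)
        start_bin = int(rng.integers(0, max(1, (chrom_len - ln) // bin_size)))
        s, e = start_bin * bin_size + 1, start_bin * bin_size + ln
        if any(overlaps((s, e), p) for p in list(placed) + list(avoid)):
            continue
        placed.append((s, e))
        covered += ln
    return sorted(placed)


def _place_events(
    sample: str, genome: GenomeModel, config: SimulationConfig, rng: np.random.Generator
) -> list[TruthEvent]:
    bs = config.bin_size
    events: list[TruthEvent] = []
    chroms = genome.names
    lengths = [genome.length(c) for c in chroms]
    weights = np.array(lengths, float) / sum(lengths)
    sep = config.min_event_separation
    for _ in range(config.events_per_sample):
        for attempt in range(2_000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            ln = int(
                np.exp(rng.uniform(math.log(config.event_length[0]), math.log(config.event_length[1])))
            )
            ln = max(bs, (ln // bs) * bs)
            max_start_bin = (genome.length(chrom) - ln) // bs
            if max_start_bin < 1:
                continue
            s = int(rng.integers(1, max_start_bin)) * bs + 1
            e = s + ln - 1
            padded = (max(1, s - sep), e + sep)
            if any(overlaps(padded, g) for g in genome.gaps.get(chrom, [])):
                continue
            if any(
                ev.chrom == chrom and overlaps(padded, (ev.start, ev.end))
                for ev in events
            ):
                continue
            base = genome.ploidy[chrom]
            if rng.random() < config.gain_prob:
                cn = int(rng.choice([c for c in config.gain_cns if c > base]))
            else:
                cn = int(rng.choice([c for c in config.loss_cns if c < base]))
            events.append(TruthEvent(sample, chrom, s, e, cn))
            break
        else:
            raise PlacementError(
                f"could not place event {len(events) + 1} for {sample} on {chrom}"
            )
    return sorted(events, key=lambda ev: (ev.chrom, ev.start))


# ---------------------------------------------------------------------------
# read depth


def expected_counts(
    genome: GenomeModel,
    truth: TruthSet,
    sample: str,
    chrom: str,
    config: SimulationConfig,
) -> np.ndarray:
    """Per-bin expected read count for one sample and chromosome.

    The mean scales with the absolute copy number relative to the diploid
    baseline (an autosomal diploid bin of average GC draws ``reads_per_bin``
    times the sample's depth multiplier; a haploid chrZ bin draws half that),
    multiplied by the GC bias at the bin's GC. Gap bins have mean 0.
    """
    bs = genome.bin_size
    nb = genome.n_bins(chrom)
    cn = np.full(nb, float(genome.ploidy[chrom]))
    for ev in truth.events_for(sample, chrom):
        cn[(ev.start - 1) // bs : (ev.end - 1 + bs) // bs] = ev.cn
    bias = gc_bias_curve(genome.gc[chrom], config.gc_bias_strength, config.gc_bias_peak)
    mu = truth.depth_multiplier[sample] * config.reads_per_bin * (cn / 2.0) * bias
    # partial last bin draws proportionally fewer reads
    last_width = genome.length(chrom) - (nb - 1) * bs
    mu[-1] *= last_width / bs
    mu[genome.gap_mask(chrom)] = 0.0
    return mu


def simulate_read_depth(
    genome: GenomeModel,
    truth: TruthSet,
    sample: str,
    config: SimulationConfig,
    seed: int | None = None,
):
    """Draw one sample's binned read-depth profile.

    Returns a :class:`rdcnv.depth.ReadDepthProfile` with raw counts (the
    corrected channel starts equal to raw; run
    :func:`rdcnv.depth.gc_correct` to populate it properly).
    """
    from .depth import ReadDepthProfile

    if sample not in truth.depth_multiplier:
        raise KeyError(f"unknown sample id {sample!r}")
    if seed is None:
        seed = config.seed
    idx = truth.samples.index(sample)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2, idx]))
    raw: dict[str, np.ndarray] = {}
    q0: dict[str, np.ndarray] = {}
    for chrom, _ in genome.chromosomes:
        mu = expected_counts(genome, truth, sample, chrom, config)
        if config.noise == "poisson":
            counts = rng.poisson(mu).astype(float)
        elif config.noise == "nb":
            # var = mu + d*mu^2  ->  gamma-poisson mixture
            d = config.nb_dispersion
            shape = 1.0 / d
            lam = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-12) * d), 0.0)
            counts = rng.poisson(lam).astype(float)
        else:
            counts = mu.copy()
        frac = np.full(mu.shape, config.q0_background)
        bs = genome.bin_size
        for s, e in genome.repeats.get(chrom, []):
            frac[(s - 1) // bs : (e - 1 + bs) // bs] = config.q0_repeat
        if config.noise != "none":
            with np.errstate(invalid="ignore"):
                n0 = rng.binomial(counts.astype(int), frac)
                frac = np.where(counts > 0, n0 / np.maximum(counts, 1), 0.0)
        frac[counts == 0] = 0.0
        raw[chrom] = counts
        q0[chrom] = frac
    return ReadDepthProfile.from_counts(sample, genome, raw, q0)


def simulate_cohort(config: SimulationConfig):
    """Convenience: genome, truth and the GC-corrected profile of every sample."""
    from .depth import gc_correct

    genome, truth = simulate_genome(config)
    profiles = {
        s: gc_correct(simulate_read_depth(genome, truth, s, config), genome)
        for s in truth.samples
    }
    return genome, truth, profiles


# ---------------------------------------------------------------------------
# aCGH

PSEUDO_CN = 0.5  # copies substituted for CN 0 when forming log2 ratios


def simulate_acgh(
    truth_test: TruthSet,
    truth_ref: TruthSet,
    genome: GenomeModel,
    config: SimulationConfig,
    test_sample: str | None = None,
    ref_sample: str | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Probe log2 ratios of a test sample against a reference sample.

    Probes sit at regular ``probe_spacing`` (skipping gaps); the expected
    value is ``log2(CN_test / CN_ref)`` at the probe position with zero
    copies replaced by ``PSEUDO_CN``, plus Gaussian noise of
    ``probe_noise_sd``. ``truth_test`` and ``truth_ref`` may be the same
    object with two different sample ids.
    """
    test_sample = test_sample or truth_test.samples[0]
    ref_sample = ref_sample or truth_ref.samples[0]
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for chrom, ln in genome.chromosomes:
        for pos in range(1, ln + 1, config.probe_spacing):
            if any(s <= pos <= e for s, e in genome.gaps.get(chrom, [])):
                continue
            cn_t = max(truth_test.cn_at(test_sample, chrom, pos, genome), PSEUDO_CN)
            cn_r = max(truth_ref.cn_at(ref_sample, chrom, pos, genome), PSEUDO_CN)
            val = math.log2(cn_t / cn_r)
            rows.append((chrom, pos, val))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "log2ratio"])
    if config.probe_noise_sd > 0:
        df["log2ratio"] += rng.normal(0.0, config.probe_noise_sd, len(df))
    return df


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    truth: TruthSet,
    primer_regions: dict[str, tuple[str, int, int]],
    reference_sample: str,
    genome: GenomeModel,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Triplicate Ct tables for the given primer regions.

    ``primer_regions`` maps a region name to ``(chrom, start, end)``. Ct
    values are constructed so that the replicate-mean ddCt of a test sample
    against ``reference_sample`` equals ``-log2(CN_test / CN_ref)`` in
    expectation; the control locus is copy-neutral in every sample. The
    reference sample must carry no CNV over any primer region.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    log_eff = math.log(config.qpcr_efficiency)
    base_target, base_control = 24.0, 20.0
    rows = []
    for name, (chrom, start, end) in primer_regions.items():
        if genome.overlaps_gap(chrom, start, end):
            raise ValueError(f"primer region {name} intersects an assembly gap")
        mid = (start + end) // 2
        ref_cn = truth.cn_at(reference_sample, chrom, mid, genome)
        if ref_cn != genome.ploidy[chrom]:
            raise ValueError(
                f"reference sample {reference_sample} carries a CNV over region {name}"
            )
        for sample in truth.samples:
            cn = max(truth.cn_at(sample, chrom, mid, genome), PSEUDO_CN)
            ct_t = base_target - math.log(cn) / log_eff
            ct_c = base_control - math.log(2.0) / log_eff
            for rep in range(1, config.qpcr_replicates + 1):
                noise_t = rng.normal(0.0, config.qpcr_ct_noise_sd) if config.qpcr_ct_noise_sd else 0.0
                noise_c = rng.normal(0.0, config.qpcr_ct_noise_sd) if config.qpcr_ct_noise_sd else 0.0
                rows.append((sample, name, rep, ct_t + noise_t, ct_c + noise_c))
    return pd.DataFrame(
        rows, columns=["sample", "region", "replicate", "Ct_target", "Ct_control"]
    )
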