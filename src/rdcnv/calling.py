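"""CNV calling from corrected read-depth signals.

The caller follows the classic read-depth recipe: partition each
chromosome's corrected RD signal into segments of presumably constant copy
number with a coarse-to-fine mean-shift procedure, test each segment's mean
against the expected neutral level, convert the surviving segments into
duplication/deletion calls with an absolute copy-number estimate, and filter
on p-value, size, the zero-mapping-quality (q0) read fraction and assembly
gap overlap.

Copy-number convention: the global mean corrected count over non-gap
autosomal bins corresponds to two copies, so for any region

    CN = 2 * (mean corrected RD over the region's non-gap bins) / global mean

regardless of chromosome; a haploid chrZ region in a female then genotypes at
~1.0 because it draws half the autosomal depth. Ploidy enters only when
deciding whether a copy number is a gain or a loss.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .depth import ReadDepthProfile
from .genome import GenomeModel
from .intervals import overlap_bp

DEFAULT_BANDWIDTHS = (2, 4, 8, 16, 32, 64, 128)
MERGE_P = 0.01  # adjacent segments merge when Welch's t gives p above this
DEVIATION_GATE = 0.25  # candidate iff mean outside [0.75, 1.25] x expected


@dataclasses.dataclass
class Segment:
    chrom: str
    start: int  # 1-based inclusive, bin-aligned
    end: int
    mean_rd: float
    n_bins: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class CNVCall:
    sample: str
    chrom: str
    start: int
    end: int
    type: str  # "duplication" | "deletion"
    cn: float
    p_value: float
    q0: float
    flags: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# segmentation


def segment_signal(
    profile: ReadDepthProfile,
    genome: GenomeModel,
    chromosome: str,
    bandwidths: Sequence[int] = DEFAULT_BANDWIDTHS,
) -> list[Segment]:
    """Mean-shift segmentation of one chromosome's corrected RD signal.

    Gap bins are masked out and each maximal run of non-gap bins is
    segmented independently, so the returned segments cover every non-gap
    bin exactly once. Within a run the 1-D mean-shift works on a positional
    shift vector: each bin is pulled toward neighbours of similar RD,

        shift_i = sum_d d * exp(-d^2 / 2h^2) * exp(-(x_{i+d} - x_i)^2 / 2s^2)

    (d over +-3h). Inside a homogeneous segment the pulls balance; a bin
    just left of a boundary is pulled left and a bin just right of it is
    pulled right, so segment boundaries sit exactly where the shift changes
    sign from negative to positive. The procedure runs over a doubling
    bandwidth schedule; after each pass adjacent segments whose bins are
    statistically indistinguishable (Welch's t, p > 0.01) are merged and the
    working signal is replaced by segment means, so fine boundaries found
    early survive the coarse passes. Finally each boundary is polished by a
    local least-squares search within +-3 bins.
    """
    mask = genome.gap_mask(chromosome)
    signal = profile.corrected[chromosome]
    sigma = max(np.sqrt(max(profile.mean, 1.0)), 1e-6)
    segments: list[Segment] = []
    n = len(signal)
    if n <= min(bandwidths):
        warnings.warn(f"{chromosome} shorter than the smallest bandwidth; single segment")
    run_start = None
    for i in range(n + 1):
        gap_here = i == n or mask[i]
        if run_start is None and not gap_here:
            run_start = i
        elif run_start is not None and gap_here:
            x = signal[run_start:i]
            for b0, b1 in _segment_run(x, bandwidths, sigma):
                s, _ = genome.bin_bounds(chromosome, run_start + b0)
                _, e = genome.bin_bounds(chromosome, run_start + b1 - 1)
                segments.append(
                    Segment(chromosome, s, e, float(x[b0:b1].mean()), b1 - b0)
                )
            run_start = None
    return segments


def _segment_run(x: np.ndarray, bandwidths: Sequence[int], sigma: float) -> list[tuple[int, int]]:
    """Segment one gap-free run; returns half-open (start, end) bin slices."""
    n = len(x)
    if n == 1:
        return [(0, 1)]
    x = x.astype(float)
    st = _RunStats(x)
    work = x.copy()
    bounds = [0, n]
    for h in bandwidths:
        if h >= n:
            break
        shift = _mean_shift_vector(work, h, sigma)
        cut = np.flatnonzero((shift[:-1] < 0) & (shift[1:] > 0)) + 1
        bounds = sorted(set(bounds) | set(cut.tolist()))
        bounds = _merge_similar(st, bounds)
        work = _piecewise_means(x, bounds)
    for _ in range(3):
        before = bounds
        bounds = _polish_boundaries(st, bounds)
        bounds = _merge_similar(st, bounds)
        if bounds == before:
            break
    return list(zip(bounds[:-1], bounds[1:]))


def _mean_shift_vector(x: np.ndarray, h: int, sigma: float) -> np.ndarray:
    shift = np.zeros(len(x))
    two_h2 = 2.0 * h * h
    two_s2 = 2.0 * sigma * sigma
    for d in range(1, 3 * h + 1):
        if d >= len(x):
            break
        k_spat = np.exp(-d * d / two_h2)
        diff = x[d:] - x[:-d]
        w = k_spat * np.exp(-(diff * diff) / two_s2)
        shift[:-d] += d * w  # pull of the right neighbour on i
        shift[d:] -= d * w  # pull of the left neighbour on i + d
    return shift


class _RunStats:
    """O(1) segment mean/variance over one gap-free run via prefix sums."""

    _tcrit_cache: np.ndarray | None = None

    def __init__(self, x: np.ndarray):
        self.x = x
        self.c1 = np.concatenate(([0.0], np.cumsum(x)))
        self.c2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def mean(self, s: int, e: int) -> float:
        return (self.c1[e] - self.c1[s]) / (e - s)

    def var(self, s: int, e: int) -> float:
        n = e - s
        if n < 2:
            return 0.0
        ss = self.c2[e] - self.c2[s] - (self.c1[e] - self.c1[s]) ** 2 / n
        return max(ss, 0.0) / (n - 1)

    @classmethod
    def _tcrit(cls, df: float) -> float:
        # two-sided critical value at MERGE_P, tabulated for speed
        if cls._tcrit_cache is None:
            cls._tcrit_cache = stats.t.ppf(1.0 - MERGE_P / 2.0, np.arange(1, 201))
        if df >= 200:
            return float(stats.norm.ppf(1.0 - MERGE_P / 2.0))
        return float(cls._tcrit_cache[max(int(df), 1) - 1])

    def indistinct(self, s: int, m: int, e: int) -> bool:
        """Should segments [s, m) and [m, e) be one segment?

        Welch's t-test with a selection-corrected threshold: the boundary at
        ``m`` was placed where the contrast looked locally largest, i.e.
        optimized over roughly as many candidate positions as the smaller
        segment could slide across. Among k candidates the most extreme
        split reaches p ~ MERGE_P / k by chance alone, so the pair stays
        split only when its p-value beats MERGE_P / (2 * min(n1, n2)).
        """
        n1, n2 = m - s, e - m
        m1, m2 = self.mean(s, m), self.mean(m, e)
        v1, v2 = self.var(s, m), self.var(m, e)
        if n1 < 2 or n2 < 2:
            pooled_sd = np.sqrt(self.var(s, e))
            return abs(m1 - m2) <= max(3.0 * pooled_sd, 1e-9)
        se2 = v1 / n1 + v2 / n2
        if se2 < 1e-24:
            return abs(m1 - m2) < 1e-9
        t = abs(m1 - m2) / np.sqrt(se2)
        df = se2 * se2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        if t < self._tcrit(df):  # not even p < MERGE_P: certainly merge
            return True
        p = 2.0 * float(stats.t.sf(t, df))
        return p > MERGE_P / (2 * min(n1, n2))


def _merge_similar(st: _RunStats, bounds: list[int]) -> list[int]:
    """Left-to-right sweeps merging adjacent indistinguishable segments."""
    while True:
        out = [bounds[0]]
        merged_any = False
        for i in range(1, len(bounds) - 1):
            if st.indistinct(out[-1], bounds[i], bounds[i + 1]):
                merged_any = True
            else:
                out.append(bounds[i])
        out.append(bounds[-1])
        bounds = out
        if not merged_any:
            return bounds


def _piecewise_means(x: np.ndarray, bounds: list[int]) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    for s, e in zip(bounds[:-1], bounds[1:]):
        out[s:e] = x[s:e].mean()
    return out


def _polish_boundaries(st: _RunStats, bounds: list[int]) -> list[int]:
    """Refit each internal boundary by exhaustive change-point search.

    For every adjacent segment pair the shared boundary moves to the
    position maximizing the two-rate quasi-Poisson likelihood over the
    pair's full span (counts are Poisson at heart, so the low-copy side is
    less noisy and the likelihood weights it accordingly); ties keep the
    position closest to the current one.
    """
    polished = list(bounds)
    for k in range(1, len(polished) - 1):
        p, q = polished[k - 1], polished[k + 1]
        cand = np.arange(p + 1, q)
        if cand.size == 0:
            continue
        left_n = cand - p
        right_n = q - cand
        left_s = st.c1[cand] - st.c1[p]
        right_s = st.c1[q] - st.c1[cand]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(left_s > 0, left_s * np.log(left_s / left_n), 0.0) + np.where(
                right_s > 0, right_s * np.log(right_s / right_n), 0.0
            )
        best = ll.max()
        ties = cand[np.isclose(ll, best)]
        polished[k] = int(ties[np.argmin(np.abs(ties - polished[k]))])
    return sorted(set(polished))


# ---------------------------------------------------------------------------
# significance testing


def test_segments(
    segments: Iterable[Segment],
    profile: ReadDepthProfile,
    genome: GenomeModel,
    deviation: float = DEVIATION_GATE,
) -> list[CNVCall]:
    """Turn deviant segments into candidate calls with p-values.

    A segment is a candidate when its mean lies outside
    ``[1 - deviation, 1 + deviation]`` times the expected neutral level of
    its chromosome (global autosomal mean scaled by ploidy/2). The attached
    p-value is a two-sided one-sample t-test of the member bins against that
    expected level. Contiguous candidates of the same direction are
    coalesced into one candidate (one CNV often segments into a few pieces
    of slightly different level; all its pieces clear the gate, so touching
    same-direction pieces are a single event) with statistics recomputed
    from the pooled bins. Single-bin deviant segments cannot be tested; they
    are kept with ``p = nan`` and a ``single-bin`` flag so the filter stage
    can reject them with an explicit reason.
    """
    out = _test_each_segment(segments, profile, genome, deviation)
    merged: list[CNVCall] = []
    for c in sorted(out, key=lambda c: (c.chrom, c.start)):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chrom == c.chrom
            and prev.type == c.type
            and c.start == prev.end + 1
        ):
            seg = Segment(c.chrom, prev.start, c.end, 0.0, 0)
            refit = _test_each_segment([seg], profile, genome, deviation=0.0)
            merged[-1] = refit[0] if refit else prev
        else:
            merged.append(c)
    return merged


def _test_each_segment(
    segments: Iterable[Segment],
    profile: ReadDepthProfile,
    genome: GenomeModel,
    deviation: float,
) -> list[CNVCall]:
    bs = profile.bin_size
    out: list[CNVCall] = []
    for seg in segments:
        expected = profile.mean * genome.ploidy[seg.chrom] / 2.0
        bins = profile.corrected[seg.chrom][(seg.start - 1) // bs : (seg.end - 1) // bs + 1]
        mask = genome.gap_mask(seg.chrom)[(seg.start - 1) // bs : (seg.end - 1) // bs + 1]
        bins = bins[~mask]
        if bins.size == 0:
            continue
        seg_mean = float(bins.mean())
        if abs(seg_mean - expected) <= deviation * expected:
            continue
        cn = 2.0 * seg_mean / profile.mean
        kind = "duplication" if cn > genome.ploidy[seg.chrom] else "deletion"
        raw = profile.raw[seg.chrom][(seg.start - 1) // bs : (seg.end - 1) // bs + 1][~mask]
        q0 = profile.q0[seg.chrom][(seg.start - 1) // bs : (seg.end - 1) // bs + 1][~mask]
        q0_frac = float((q0 * raw).sum() / raw.sum()) if raw.sum() > 0 else float(q0.mean()) if q0.size else 0.0
        flags: tuple[str, ...] = ()
        if len(bins) < 2:
            p = float("nan")
            flags = ("single-bin",)
        elif bins.std(ddof=1) < 1e-12:
            p = 0.0 if abs(bins.mean() - expected) > 1e-9 else 1.0
        else:
            p = float(stats.ttest_1samp(bins, popmean=expected).pvalue)
        out.append(
            CNVCall(profile.sample, seg.chrom, seg.start, seg.end, kind, cn, p, q0_frac, flags)
        )
    return out


# ---------------------------------------------------------------------------
# filtering


def apply_filters(
    candidates: Iterable[CNVCall],
    genome: GenomeModel,
    p_max: float = 0.01,
    min_len: int = 1_000,
    q0_max: float = 0.5,
    keep_gap_calls: bool = False,
    merge_across_gaps: bool = True,
) -> tuple[list[CNVCall], pd.DataFrame]:
    """Apply the stringent call filters; returns (calls, rejection log).

    A candidate survives iff p < ``p_max`` AND length > ``min_len`` AND q0
    fraction <= ``q0_max`` AND it overlaps no assembly gap (the gap gate can
    be disabled with ``keep_gap_calls`` to reproduce raw-mode re-inspection
    of gap-spanning loci). Every rejection is logged with all failing
    reasons. Surviving same-type calls of one sample separated only by gap
    bins are merged into one call.
    """
    kept: list[CNVCall] = []
    log_rows = []
    for c in candidates:
        reasons = []
        if "single-bin" in c.flags or not np.isfinite(c.p_value):
            reasons.append("single-bin")
        elif c.p_value >= p_max:
            reasons.append("pvalue")
        if c.length <= min_len:
            reasons.append("size")
        if c.q0 > q0_max:
            reasons.append("q0")
        overlaps_gap = genome.overlaps_gap(c.chrom, c.start, c.end)
        if overlaps_gap and not keep_gap_calls:
            reasons.append("gap")
        if reasons:
            log_rows.append(
                (c.sample, c.chrom, c.start, c.end, c.type, c.cn, c.p_value, c.q0, ",".join(reasons))
            )
        else:
            flags = c.flags + (("gap-overlap",) if overlaps_gap else ())
            kept.append(dataclasses.replace(c, flags=flags))
    if merge_across_gaps:
        kept = _merge_gap_separated(kept, genome)
    log = pd.DataFrame(
        log_rows,
        columns=["sample", "chrom", "start", "end", "type", "cn", "p_value", "q0", "reason"],
    )
    return kept, log


def _merge_gap_separated(calls: list[CNVCall], genome: GenomeModel) -> list[CNVCall]:
    calls = sorted(calls, key=lambda c: (c.sample, c.chrom, c.start))
    out: list[CNVCall] = []
    for c in calls:
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.sample == c.sample
            and prev.chrom == c.chrom
            and prev.type == c.type
            and c.start > prev.end
            and _all_gap_between(genome, c.chrom, prev.end + 1, c.start - 1)
        ):
            w1, w2 = prev.length, c.length
            out[-1] = dataclasses.replace(
                prev,
                end=c.end,
                cn=(prev.cn * w1 + c.cn * w2) / (w1 + w2),
                p_value=min(prev.p_value, c.p_value),
                q0=(prev.q0 * w1 + c.q0 * w2) / (w1 + w2),
                flags=tuple(sorted(set(prev.flags + c.flags + ("gap-merged",)))),
            )
        else:
            out.append(c)
    return out


def _all_gap_between(genome: GenomeModel, chrom: str, start: int, end: int) -> bool:
    if start > end:
        return True
    covered = sum(overlap_bp((start, end), g) for g in genome.gaps.get(chrom, []))
    return covered >= end - start + 1


# ---------------------------------------------------------------------------
# genotyping


def genotype_region(
    profile: ReadDepthProfile,
    region: tuple[str, int, int],
    genome: GenomeModel,
) -> float:
    """Absolute copy number of an arbitrary region (nan when wholly in gaps).

    CN = 2 * mean corrected RD over the region's non-gap bins / global
    autosomal mean. Bins overlapping the region by any amount contribute.
    """
    chrom, start, end = region
    if chrom not in profile.corrected:
        raise KeyError(chrom)
    bs = profile.bin_size
    b0, b1 = (start - 1) // bs, (end - 1) // bs + 1
    vals = profile.corrected[chrom][b0:b1]
    mask = genome.gap_mask(chrom)[b0:b1]
    vals = vals[~mask]
    if vals.size == 0:
        return float("nan")
    return float(2.0 * vals.mean() / profile.mean)


def genotype_windows(
    profile: ReadDepthProfile,
    genome: GenomeModel,
    window: int = 5_000,
    exclude: Sequence[tuple[str, int, int]] = (),
) -> tuple[pd.DataFrame, float, float]:
    """Copy number of all autosomal windows clear of the excluded intervals.

    Windows intersecting (>= 1 bp) any excluded interval or assembly gap are
    dropped, as is the trailing partial window of each chromosome. Returns
    the per-window table plus the mean and sample STDEV of the window CNs.
    """
    if window < profile.bin_size:
        raise ValueError("window must be at least one bin")
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in exclude:
        excl_by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in genome.names:
        excl_by_chrom.setdefault(chrom, []).extend(genome.gaps.get(chrom, []))
    rows = []
    for chrom in genome.autosomes():
        ln = genome.length(chrom)
        for s in range(1, ln - window + 2, window):
            e = s + window - 1
            if any(overlap_bp((s, e), iv) > 0 for iv in excl_by_chrom.get(chrom, [])):
                continue
            rows.append((chrom, s, e, genotype_region(profile, (chrom, s, e), genome)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    if df.empty:
        return df, float("nan"), float("nan")
    cns = df["cn"].dropna().to_numpy()
    mean = float(cns.mean()) if cns.size else float("nan")
    stdev = float(cns.std(ddof=1)) if cns.size > 1 else 0.0
    return df, mean, stdev


# ---------------------------------------------------------------------------
# pipeline convenience


def call_cnvs(
    profile: ReadDepthProfile,
    genome: GenomeModel,
    bandwidths: Sequence[int] = DEFAULT_BANDWIDTHS,
    p_max: float = 0.01,
    min_len: int = 1_000,
    q0_max: float = 0.5,
    keep_gap_calls: bool = False,
) -> tuple[list[CNVCall], pd.DataFrame]:
    """Segment, test and filter every chromosome of one sample."""
    candidates: list[CNVCall] = []
    for chrom in genome.names:
        segs = segment_signal(profile, genome, chrom, bandwidths)
        candidates.extend(test_segments(segs, profile, genome))
    return apply_filters(
        candidates, genome, p_max=p_max, min_len=min_len, q0_max=q0_max,
        keep_gap_calls=keep_gap_calls,
    )
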