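"""Binned read-depth signals and GC-bias correction.

The read-depth (RD) signal is the count of mapped reads whose leftmost
aligned position falls in each non-overlapping bin of fixed size. Sequencers
over- or under-sample fragments depending on their GC content; the correction
rescales each bin by the ratio of the global mean count to the mean count of
all bins sharing its GC stratum, so that copy number — not base composition —
drives the corrected signal.
"""

from __future__ import annotations

import dataclasses
from os import PathLike
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import GenomeModel

GC_STRATUM_WIDTH = 0.01  # 1% GC strata
MIN_STRATUM_BINS = 100  # below this, fall back to the global mean


@dataclasses.dataclass
class ReadDepthProfile:
    """One sample's per-bin raw and corrected read counts.

    ``raw``, ``corrected`` and ``q0`` map chromosome name to per-bin arrays;
    ``mean``/``stdev`` summarize the corrected signal over non-gap autosomal
    bins and anchor all copy-number ratios downstream (the mean corresponds to
    two copies).
    """

    sample: str
    bin_size: int
    raw: dict[str, np.ndarray]
    corrected: dict[str, np.ndarray]
    q0: dict[str, np.ndarray]
    mean: float = float("nan")
    stdev: float = float("nan")
    gc_corrected: bool = False

    @classmethod
    def from_counts(
        cls,
        sample: str,
        genome: GenomeModel,
        raw: Mapping[str, np.ndarray],
        q0: Mapping[str, np.ndarray] | None = None,
    ) -> "ReadDepthProfile":
        raw = {c: np.asarray(v, dtype=float) for c, v in raw.items()}
        if q0 is None:
            q0 = {c: np.zeros_like(v) for c, v in raw.items()}
        prof = cls(
            sample=sample,
            bin_size=genome.bin_size,
            raw=raw,
            corrected={c: v.copy() for c, v in raw.items()},
            q0={c: np.asarray(v, dtype=float) for c, v in q0.items()},
        )
        prof.refresh_stats(genome)
        return prof

    def autosomal_values(self, genome: GenomeModel, channel: str = "corrected") -> np.ndarray:
        """Concatenated non-gap autosomal bin values of one channel."""
        parts = []
        for chrom in genome.autosomes():
            if chrom not in getattr(self, channel):
                continue
            vals = getattr(self, channel)[chrom]
            parts.append(vals[~genome.gap_mask(chrom)])
        if not parts:
            raise ValueError("profile has no non-gap autosomal bins")
        return np.concatenate(parts)

    def refresh_stats(self, genome: GenomeModel) -> None:
        """Set ``mean`` to the diploid RD level and ``stdev`` to the bin STDEV.

        The diploid level is the per-bin mean of neutral autosomal windows,
        found by iteratively trimming windows deviating more than 25% from
        the current estimate (CNV-carrying windows would otherwise inflate
        the plain mean and bias every copy-number ratio downstream). Windows
        aggregate enough bins that the trimming separates copy-number states
        cleanly while clipping essentially no neutral windows.
        """
        vals = self.autosomal_values(genome)
        self.stdev = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        k = max(1, 5_000 // self.bin_size)
        parts = []
        for chrom in genome.autosomes():
            if chrom not in self.corrected:
                continue
            v = self.corrected[chrom]
            m = genome.gap_mask(chrom)
            n_full = len(v) // k
            if n_full:
                vv = v[: n_full * k].reshape(n_full, k)
                mm = m[: n_full * k].reshape(n_full, k)
                parts.append(vv.mean(axis=1)[~mm.any(axis=1)])
        w = np.concatenate(parts) if parts else vals.reshape(1, -1).mean(axis=1)
        if w.size == 0:
            w = np.array([vals.mean()])
        mu = float(np.median(w))
        spread = 1.4826 * float(np.median(np.abs(w - mu)))  # robust window SD
        tol = max(4.0 * spread, 1e-9 * max(mu, 1.0))
        for _ in range(5):
            band = w[np.abs(w - mu) <= min(tol, 0.25 * mu)]
            if band.size == 0:
                break
            mu = float(band.mean())
        self.mean = mu

    def to_frame(self, genome: GenomeModel) -> pd.DataFrame:
        rows = []
        for chrom in self.raw:
            n = len(self.raw[chrom])
            starts = np.arange(n) * self.bin_size + 1
            ends = np.minimum(starts + self.bin_size - 1, genome.length(chrom))
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "bin_start": starts,
                        "bin_end": ends,
                        "raw": self.raw[chrom],
                        "corrected": self.corrected[chrom],
                        "q0_frac": self.q0[chrom],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def bin_counts(
    source,
    genome: GenomeModel,
    bin_size: int | None = None,
    sample: str = "sample",
) -> ReadDepthProfile:
    """Build a :class:`ReadDepthProfile` from an alignment file or depth table.

    ``source`` may be a path to a SAM/BAM/CRAM file (read via pysam), an open
    ``pysam.AlignmentFile``, a path to a depth TSV (columns ``chrom``,
    ``bin_start``, ``bin_end``, ``count``, ``q0_frac``), or a DataFrame of
    that shape. Each read is assigned to exactly one bin by its leftmost
    aligned position; unmapped, secondary and supplementary records are
    skipped, and the per-bin q0 fraction is the share of assigned reads with
    mapping quality 0.
    """
    bs = bin_size or genome.bin_size
    if bs < 1:
        raise ValueError("bin_size must be >= 1")
    if bs != genome.bin_size:
        raise ValueError(
            f"bin_size {bs} differs from the genome model's {genome.bin_size}; "
            "rebuild the GenomeModel at the calling bin size"
        )
    if isinstance(source, pd.DataFrame):
        return _profile_from_table(source, genome, sample)
    if isinstance(source, (str, PathLike)):
        text = str(source)
        if text.endswith((".sam", ".bam", ".cram")):
            import pysam

            with pysam.AlignmentFile(text) as af:
                return _profile_from_alignments(af, genome, bs, sample)
        from .io import read_depth_table

        return _profile_from_table(read_depth_table(text), genome, sample)
    # assume an open pysam.AlignmentFile-like iterable of reads
    return _profile_from_alignments(source, genome, bs, sample)


def _profile_from_alignments(af, genome: GenomeModel, bs: int, sample: str) -> ReadDepthProfile:
    counts = {c: np.zeros(genome.n_bins(c, bs)) for c in genome.names}
    q0_counts = {c: np.zeros(genome.n_bins(c, bs)) for c in genome.names}
    unknown: set[str] = set()
    for read in af:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        chrom = read.reference_name
        if chrom not in counts:
            unknown.add(chrom)
            continue
        b = read.reference_start // bs  # 0-based leftmost -> bin index
        counts[chrom][b] += 1
        if read.mapping_quality == 0:
            q0_counts[chrom][b] += 1
    if unknown:
        raise ValueError(
            "alignment chromosomes absent from genome model: " + ", ".join(sorted(unknown))
        )
    q0 = {
        c: np.where(counts[c] > 0, q0_counts[c] / np.maximum(counts[c], 1), 0.0)
        for c in counts
    }
    return ReadDepthProfile.from_counts(sample, genome, counts, q0)


def _profile_from_table(df: pd.DataFrame, genome: GenomeModel, sample: str) -> ReadDepthProfile:
    unknown = set(df["chrom"]) - set(genome.names)
    if unknown:
        raise ValueError(
            "depth-table chromosomes absent from genome model: " + ", ".join(sorted(unknown))
        )
    counts, q0 = {}, {}
    for chrom, sub in df.groupby("chrom", sort=False):
        n = genome.n_bins(chrom)
        arr = np.zeros(n)
        qarr = np.zeros(n)
        idx = (sub["bin_start"].to_numpy() - 1) // genome.bin_size
        arr[idx] = sub["count"].to_numpy(dtype=float)
        if "q0_frac" in sub:
            qarr[idx] = sub["q0_frac"].to_numpy(dtype=float)
        counts[chrom] = arr
        q0[chrom] = qarr
    for chrom in genome.names:  # chromosomes absent from the table are all-zero
        counts.setdefault(chrom, np.zeros(genome.n_bins(chrom)))
        q0.setdefault(chrom, np.zeros(genome.n_bins(chrom)))
    return ReadDepthProfile.from_counts(sample, genome, counts, q0)


def gc_correct(profile: ReadDepthProfile, genome: GenomeModel) -> ReadDepthProfile:
    """GC-stratified mean rescaling of the raw counts.

    corrected_i = raw_i * m_global / m_gc(stratum of bin i), with strata of
    1% GC width. Both m_global and the stratum means are computed over
    non-gap *autosomal* bins; strata holding fewer than ``MIN_STRATUM_BINS``
    bins fall back to the global mean (no correction). Gap bins are left
    untouched.

    Because GC varies slowly along the genome, the bins of a single CNV tend
    to fall into few strata and would drag those stratum means toward the
    event's copy number, over-correcting the event and distorting nearby
    neutral bins. The estimate therefore runs twice: a first pass corrects
    with plain stratum means, copy-number-deviant windows (5 kb window mean
    off the diploid level by more than 25%) are masked, and the stratum
    means are re-estimated from the remaining bins before the final
    correction. The global mean is preserved to within ~1% and the operation
    is idempotent (it always starts from the raw channel).
    """
    strata = {
        c: np.minimum((genome.gc[c] / GC_STRATUM_WIDTH).astype(int), 99) for c in genome.names
    }
    base_keep = {c: ~genome.gap_mask(c) for c in genome.names}
    if not any(base_keep[c].any() for c in genome.autosomes()):
        raise ValueError("no non-gap autosomal bins available for GC correction")

    corrected = _apply_stratum_correction(profile, genome, strata, base_keep)
    # mask copy-number-deviant windows and re-estimate the bias, iterating:
    # heavily contaminated strata distort the first pass enough that their
    # events do not look deviant yet, so repeat until the mask stabilizes.
    # 1 kb masking windows: long enough to average out counting noise at the
    # 25% threshold, short enough that even minimum-length events trip it
    k = max(2, 1_000 // profile.bin_size)
    prev_keep: dict[str, np.ndarray] | None = None
    for _ in range(4):
        current = dataclasses.replace(profile, corrected=corrected, gc_corrected=True)
        current.refresh_stats(genome)
        neutral_keep = {}
        for chrom in genome.names:
            keep = base_keep[chrom].copy()
            v = corrected[chrom]
            n_full = len(v) // k
            if n_full and current.mean > 0:
                wmeans = v[: n_full * k].reshape(n_full, k).mean(axis=1)
                deviant = np.abs(wmeans - current.mean) > 0.25 * current.mean
                # dilate by one window: windows part-covering an event pass
                # the threshold yet still hold event bins that skew strata
                core = deviant.copy()
                deviant[1:] |= core[:-1]
                deviant[:-1] |= core[1:]
                keep[: n_full * k] &= ~np.repeat(deviant, k)
                keep[n_full * k :] = False  # trailing partial window
            neutral_keep[chrom] = keep
        if not any(neutral_keep[c].any() for c in genome.autosomes()):
            break
        if prev_keep is not None and all(
            np.array_equal(neutral_keep[c], prev_keep[c]) for c in genome.names
        ):
            break
        corrected = _apply_stratum_correction(profile, genome, strata, neutral_keep)
        prev_keep = neutral_keep
    out = dataclasses.replace(profile, corrected=corrected, gc_corrected=True)
    out.refresh_stats(genome)
    return out


def _apply_stratum_correction(
    profile: ReadDepthProfile,
    genome: GenomeModel,
    strata: Mapping[str, np.ndarray],
    keep: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    sums = np.zeros(100)
    nums = np.zeros(100, dtype=int)
    for chrom in genome.autosomes():
        sel = keep[chrom]
        np.add.at(sums, strata[chrom][sel], profile.raw[chrom][sel])
        np.add.at(nums, strata[chrom][sel], 1)
    m_global = sums.sum() / max(nums.sum(), 1)
    m_gc = np.where(nums >= MIN_STRATUM_BINS, sums / np.maximum(nums, 1), m_global)
    m_gc = np.where(m_gc > 0, m_gc, m_global)
    corrected = {}
    for chrom in genome.names:
        vals = profile.raw[chrom].astype(float).copy()
        nz = ~genome.gap_mask(chrom)
        vals[nz] = vals[nz] * (m_global / m_gc[strata[chrom][nz]])
        corrected[chrom] = vals
    return corrected


def profile_stats(
    profile: ReadDepthProfile, genome: GenomeModel, window: int = 5_000
) -> tuple[float, float]:
    """Mean and sample STDEV of corrected counts summed over autosomal windows.

    Windows are non-overlapping multiples of the bin size; windows that
    intersect an assembly gap, and the trailing partial window of each
    chromosome, are excluded.
    """
    totals = window_totals(profile, genome, window)
    if totals.size == 0:
        raise ValueError("no gap-free autosomal windows")
    mean = float(totals.mean())
    stdev = float(totals.std(ddof=1)) if totals.size > 1 else 0.0
    return mean, stdev


def window_totals(profile: ReadDepthProfile, genome: GenomeModel, window: int) -> np.ndarray:
    if window % profile.bin_size:
        raise ValueError("window must be a multiple of the bin size")
    k = window // profile.bin_size
    parts = []
    for chrom in genome.autosomes():
        vals = profile.corrected[chrom]
        mask = genome.gap_mask(chrom)
        n_full = len(vals) // k
        if n_full == 0:
            continue
        v = vals[: n_full * k].reshape(n_full, k)
        m = mask[: n_full * k].reshape(n_full, k)
        keep = ~m.any(axis=1)
        parts.append(v[keep].sum(axis=1))
    return np.concatenate(parts) if parts else np.empty(0)
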