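"""Genome reference model: chromosome sizes, per-bin GC, assembly gaps, ploidy.

The model carries everything the depth pipeline needs to know about the
reference assembly: an ordered chromosome list, the GC fraction of each
fixed-size bin (used for GC-bias correction), assembly gap intervals (bins in
gaps carry no reads and are masked throughout), and the per-chromosome copy
number baseline. All samples in the study design are female, so autosomes are
diploid (baseline 2) and the Z sex chromosome is haploid (baseline 1).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import merge_intervals, overlap_bp

AUTOSOME_PLOIDY = 2


@dataclasses.dataclass
class GenomeModel:
    """Reference genome description at a fixed bin size.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    bin_size:
        Width in bp of the bins at which ``gc`` is tabulated; also the default
        bin size of the depth pipeline.
    gc:
        Mapping chromosome -> per-bin GC fraction in ``[0, 1]`` (last bin may
        be partial).
    gaps:
        Mapping chromosome -> list of assembly gap intervals, 1-based
        inclusive. Missing chromosomes have no gaps.
    ploidy:
        Mapping chromosome -> baseline copy number (2 for autosomes, 1 for
        chrZ of a female).
    repeats:
        Optional intervals with ambiguous (zero mapping quality) placement,
        used by the simulator to drive the q0 fraction.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    gc: dict[str, np.ndarray]
    gaps: dict[str, list[tuple[int, int]]]
    ploidy: dict[str, int]
    repeats: dict[str, list[tuple[int, int]]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        for chrom in names:
            if chrom not in self.ploidy:
                raise ValueError(f"chromosome {chrom} has no ploidy entry")
            g = np.asarray(self.gc.get(chrom, np.empty(0)), dtype=float)
            if g.size and (g.min() < 0 or g.max() > 1):
                raise ValueError(f"GC fractions outside [0, 1] on {chrom}")
            self.gc[chrom] = g
            for s, e in self.gaps.get(chrom, []):
                if s < 1 or e > lengths[chrom] or e < s:
                    raise ValueError(f"gap ({s}, {e}) outside {chrom} bounds")

    # -- basic geometry -----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for c, n in self.chromosomes:
            if c == chrom:
                return n
        raise KeyError(chrom)

    def autosomes(self) -> list[str]:
        return [c for c, _ in self.chromosomes if self.ploidy[c] == AUTOSOME_PLOIDY]

    def n_bins(self, chrom: str, bin_size: int | None = None) -> int:
        bs = bin_size or self.bin_size
        return -(-self.length(chrom) // bs)

    def bin_bounds(self, chrom: str, idx: int, bin_size: int | None = None) -> tuple[int, int]:
        """1-based inclusive coordinates of bin ``idx`` (0-based index)."""
        bs = bin_size or self.bin_size
        return idx * bs + 1, min((idx + 1) * bs, self.length(chrom))

    # -- gap handling -------------------------------------------------------

    def gap_mask(self, chrom: str, bin_size: int | None = None) -> np.ndarray:
        """Boolean per-bin mask: True where at least half the bin lies in a gap."""
        bs = bin_size or self.bin_size
        n = self.n_bins(chrom, bs)
        mask = np.zeros(n, dtype=bool)
        for s, e in self.gaps.get(chrom, []):
            first = (s - 1) // bs
            last = (e - 1) // bs
            for i in range(first, min(last + 1, n)):
                b = self.bin_bounds(chrom, i, bs)
                if overlap_bp(b, (s, e)) * 2 >= (b[1] - b[0] + 1):
                    mask[i] = True
        return mask

    def overlaps_gap(self, chrom: str, start: int, end: int) -> bool:
        return any(overlap_bp((start, end), g) > 0 for g in self.gaps.get(chrom, []))


def genome_from_files(
    fasta_path: str,
    bin_size: int,
    gaps_bed: str | None = None,
    ploidy: Mapping[str, int] | None = None,
    female: bool = True,
) -> GenomeModel:
    """Build a :class:`GenomeModel` from a FASTA (+ optional gaps BED).

    GC is computed per bin from the sequence; ``N`` runs of at least
    ``bin_size`` bp are added to the gap list automatically. Ploidy defaults to
    2 everywhere except chromosomes named ``chrZ``/``Z`` when ``female``.
    """
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    chromosomes = [(name, len(fa[name])) for name in fa.keys()]
    gc: dict[str, np.ndarray] = {}
    gaps: dict[str, list[tuple[int, int]]] = {}
    for name, ln in chromosomes:
        seq = np.frombuffer(str(fa[name][:]).upper().encode(), dtype="S1")
        is_gc = (seq == b"G") | (seq == b"C")
        is_n = seq == b"N"
        nb = -(-ln // bin_size)
        vals = np.empty(nb)
        for i in range(nb):
            s, e = i * bin_size, min((i + 1) * bin_size, ln)
            known = e - s - int(is_n[s:e].sum())
            vals[i] = is_gc[s:e].sum() / known if known else 0.0
        gc[name] = vals
        gaps[name] = _n_runs(is_n, min_len=bin_size)
    if gaps_bed is not None:
        from .io import read_bed_intervals

        for chrom, s, e in read_bed_intervals(gaps_bed):
            gaps.setdefault(chrom, []).append((s, e))
        gaps = {c: merge_intervals(v) for c, v in gaps.items()}
    if ploidy is None:
        ploidy = {
            name: (1 if female and name.lstrip("chr").upper() == "Z" else AUTOSOME_PLOIDY)
            for name, _ in chromosomes
        }
    return GenomeModel(chromosomes, bin_size, gc, gaps, dict(ploidy))


def _n_runs(is_n: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    out = []
    diff = np.diff(np.concatenate(([0], is_n.astype(np.int8), [0])))
    for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
        if e - s >= min_len:
            out.append((int(s) + 1, int(e)))
    return out
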