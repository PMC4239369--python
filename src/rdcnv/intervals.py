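"""Small helpers for 1-based inclusive genomic intervals.

Every public interval in this package is a ``(start, end)`` pair of 1-based
inclusive coordinates, matching the convention of the emitted tables. BED
output converts to 0-based half-open at the I/O boundary only.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def length(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0] + 1


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of shared bases between two 1-based inclusive intervals (0 if none)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return overlap_bp(a, b) > 0


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; overlapping or abutting intervals are fused."""
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(ivs: Sequence[tuple[int, int]]) -> int:
    return sum(length(iv) for iv in merge_intervals(ivs))


def subtract(iv: tuple[int, int], cuts: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of ``iv`` not covered by any interval in ``cuts``."""
    pieces = []
    pos = iv[0]
    for s, e in merge_intervals(cuts):
        if e < iv[0] or s > iv[1]:
            continue
        if s > pos:
            pieces.append((pos, min(s - 1, iv[1])))
        pos = max(pos, e + 1)
    if pos <= iv[1]:
        pieces.append((pos, iv[1]))
    return pieces
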