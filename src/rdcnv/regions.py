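"""Multi-sample CNV regions: merging, classification, summaries and overlaps.

A CNV region (CNVR) is the union of CNV calls from different samples that
share at least 1 bp, merged transitively. A CNVR is classed *gain* when all
member calls are duplications, *loss* when all are deletions, and *both*
otherwise. The module also overlays CNVRs on gene annotation, QTL confidence
intervals and external CNVR sets, and ranks genes by the variability of
their copy-number estimates across samples.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import CNVCall
from .genome import GenomeModel
from .intervals import merge_intervals, overlap_bp


@dataclasses.dataclass
class CNVR:
    id: str
    chrom: str
    start: int
    end: int
    cls: str  # "gain" | "loss" | "both"
    carriers: dict[str, str]  # sample -> "duplication"/"deletion"/"both"
    members: list[CNVCall] = dataclasses.field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def frequency(self) -> int:
        return len(self.carriers)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    symbol: str
    transcript: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclasses.dataclass(frozen=True)
class QTLRecord:
    trait: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# merging and classification


def merge_to_cnvrs(calls: Iterable[CNVCall], id_prefix: str = "CNVR") -> list[CNVR]:
    """Single-linkage merge of per-sample calls into CNVRs (>= 1 bp overlap).

    Calls sharing at least one base are transitively merged; abutting calls
    (0 bp shared) stay separate. Ids are assigned in genome order
    (chromosome name, start).
    """
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    out: list[CNVR] = []
    for chrom in sorted(by_chrom):
        group: list[CNVCall] = []
        end = -1
        for c in sorted(by_chrom[chrom], key=lambda c: (c.start, c.end)):
            if group and c.start <= end:  # 1-based inclusive: >=1 bp shared
                group.append(c)
                end = max(end, c.end)
            else:
                if group:
                    out.append(_build_cnvr(chrom, group))
                group = [c]
                end = c.end
        if group:
            out.append(_build_cnvr(chrom, group))
    for i, r in enumerate(out, start=1):
        r.id = f"{id_prefix}{i}"
    return out


def _build_cnvr(chrom: str, members: list[CNVCall]) -> CNVR:
    carriers: dict[str, str] = {}
    for c in members:
        prev = carriers.get(c.sample)
        carriers[c.sample] = c.type if prev in (None, c.type) else "both"
    r = CNVR(
        id="",
        chrom=chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        cls="",
        carriers=carriers,
        members=list(members),
    )
    r.cls = classify_cnvr(r)
    return r


def classify_cnvr(cnvr: CNVR) -> str:
    kinds = {c.type for c in cnvr.members}
    if kinds == {"duplication"}:
        return "gain"
    if kinds == {"deletion"}:
        return "loss"
    return "both"


# ---------------------------------------------------------------------------
# summaries


def summarize_cnvrs(cnvrs: Sequence[CNVR], genome: GenomeModel | None = None) -> dict:
    """Descriptive statistics of a CNVR set.

    Returns a dict with scalar totals, a size-class histogram, frequency
    classes (unique / shared by 2 / shared by >= 3), per-class (gain, loss,
    both) counts and lengths, and — when a genome is given — a
    per-chromosome table with count and density (mean distance between
    CNVRs, i.e. chromosome length / count).
    """
    lengths = np.array([r.length for r in cnvrs], dtype=float)
    freqs = np.array([r.frequency for r in cnvrs])
    summary: dict = {
        "n_cnvrs": len(cnvrs),
        "total_length_bp": int(lengths.sum()) if len(cnvrs) else 0,
        "length_min_bp": float(lengths.min()) if len(cnvrs) else float("nan"),
        "length_mean_bp": float(lengths.mean()) if len(cnvrs) else float("nan"),
        "length_median_bp": float(np.median(lengths)) if len(cnvrs) else float("nan"),
        "length_max_bp": float(lengths.max()) if len(cnvrs) else float("nan"),
    }
    size_edges = [(0, 10_000, "<=10kb"), (10_000, 50_000, "10-50kb"), (50_000, None, ">50kb")]
    size_rows = []
    for lo, hi, label in size_edges:
        n = int(((lengths > lo) & (lengths <= (hi or np.inf))).sum())
        size_rows.append((label, n, 100.0 * n / max(len(cnvrs), 1)))
    summary["size_classes"] = pd.DataFrame(size_rows, columns=["class", "count", "percent"])

    freq_rows = []
    for label, sel in [
        ("unique", freqs == 1),
        ("shared_by_2", freqs == 2),
        ("shared_by_3_or_more", freqs >= 3),
    ]:
        sub = lengths[sel]
        freq_rows.append(
            (
                label,
                int(sel.sum()),
                100.0 * sel.sum() / max(len(cnvrs), 1),
                float(sub.mean()) if sub.size else float("nan"),
                float(np.median(sub)) if sub.size else float("nan"),
            )
        )
    summary["frequency_classes"] = pd.DataFrame(
        freq_rows, columns=["class", "count", "percent", "mean_length_bp", "median_length_bp"]
    )

    cls_rows = []
    for cls in ("gain", "loss", "both"):
        sub = [r for r in cnvrs if r.cls == cls]
        tot = sum(r.length for r in sub)
        cls_rows.append((cls, len(sub), tot, tot / len(sub) if sub else float("nan")))
    summary["classes"] = pd.DataFrame(
        cls_rows, columns=["class", "count", "total_length_bp", "mean_length_bp"]
    )

    if genome is not None:
        chrom_rows = []
        for chrom, ln in genome.chromosomes:
            n = sum(1 for r in cnvrs if r.chrom == chrom)
            chrom_rows.append((chrom, n, ln / n if n else float("nan")))
        summary["per_chromosome"] = pd.DataFrame(
            chrom_rows, columns=["chrom", "count", "density_bp"]
        )
    return summary


def interval_distance(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> tuple[int, bool]:
    """Distance in bp between two loci: start(b) - end(a).

    Returns ``(distance, overlap_flag)``; overlapping or abutting intervals
    report distance 0 with the flag set. Intervals must share a chromosome
    and ``a`` must not start after ``b``.
    """
    if a[0] != b[0]:
        raise ValueError(f"intervals on different chromosomes: {a[0]} vs {b[0]}")
    if a[1] > b[1]:
        a, b = b, a
    d = b[1] - a[2]
    return (d, False) if d > 0 else (0, True)


# ---------------------------------------------------------------------------
# cross-set and annotation overlaps


def compare_cnvr_sets(
    set_a: Sequence[CNVR],
    set_b: Sequence[tuple[str, int, int] | CNVR],
    b_sources: Sequence[str] | None = None,
) -> dict:
    """Flag each region of ``set_a`` as overlapped (>= 1 bp with ``set_b``) or novel.

    ``set_b`` entries may be plain ``(chrom, start, end)`` tuples; optional
    ``b_sources`` labels (one per ``set_b`` entry) yield a per-source
    breakdown of how many ``set_a`` regions each source recovers.
    """
    b_ivs = [
        (r.chrom, r.start, r.end) if isinstance(r, CNVR) else tuple(r) for r in set_b
    ]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, (chrom, s, e) in enumerate(b_ivs):
        by_chrom.setdefault(chrom, []).append((s, e, j))
    flags, hit_sources = [], []
    for r in set_a:
        hits = [
            j
            for s, e, j in by_chrom.get(r.chrom, [])
            if overlap_bp((r.start, r.end), (s, e)) > 0
        ]
        flags.append(bool(hits))
        hit_sources.append(hits)
    n_over = sum(flags)
    report = {
        "n_total": len(set_a),
        "n_overlapped": n_over,
        "n_novel": len(set_a) - n_over,
        "pct_overlapped": 100.0 * n_over / max(len(set_a), 1),
        "pct_novel": 100.0 * (len(set_a) - n_over) / max(len(set_a), 1),
        "overlapped_length_bp": sum(r.length for r, f in zip(set_a, flags) if f),
        "flags": flags,
    }
    if b_sources is not None:
        per_source = {}
        for src in sorted(set(b_sources)):
            idx = {j for j, s in enumerate(b_sources) if s == src}
            n = sum(1 for hits in hit_sources if idx & set(hits))
            per_source[src] = n
        report["per_source"] = per_source
    return report


def overlap_genes(cnvrs: Sequence[CNVR], genes: Sequence[GeneRecord]) -> dict:
    """Gene/CNVR overlap table with completeness flags and two-sided percentages."""
    by_chrom: dict[str, list[CNVR]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    hit_cnvrs: set[str] = set()
    for g in genes:
        hits = [
            r
            for r in by_chrom.get(g.chrom, [])
            if overlap_bp(g.interval, r.interval) > 0
        ]
        if not hits:
            continue
        hit_cnvrs.update(r.id for r in hits)
        ov = sum(
            e - s + 1
            for s, e in merge_intervals(
                [
                    (max(g.start, r.start), min(g.end, r.end))
                    for r in hits
                ]
            )
        )
        complete = ov == g.end - g.start + 1
        rows.append((g.symbol, g.transcript, g.chrom, g.start, g.end,
                     ";".join(r.id for r in hits), ov, complete))
    table = pd.DataFrame(
        rows,
        columns=["symbol", "transcript", "chrom", "start", "end", "cnvr_ids",
                 "overlap_bp", "complete"],
    )
    return {
        "genes": table,
        "n_genes_overlapping": len(table),
        "pct_genes_overlapping": 100.0 * len(table) / max(len(genes), 1),
        "n_genes_complete": int(table["complete"].sum()) if len(table) else 0,
        "n_cnvrs_with_genes": len(hit_cnvrs),
        "pct_cnvrs_with_genes": 100.0 * len(hit_cnvrs) / max(len(cnvrs), 1),
    }


def rank_variable_genes(cn_matrix: pd.DataFrame, top: int | None = None) -> pd.DataFrame:
    """Rank genes by the sample STDEV of their per-sample copy numbers.

    ``cn_matrix`` is genes (rows, indexed by symbol) x samples. Rows with any
    undefined CN are excluded and flagged in the ``excluded`` attribute of
    the result (``result.attrs['excluded']``). Ties in STDEV break by symbol.
    """
    complete = cn_matrix.dropna(axis=0)
    out = complete.copy()
    out["cn_stdev"] = complete.std(axis=1, ddof=1)
    order = sorted(out.index, key=lambda sym: (-out.loc[sym, "cn_stdev"], str(sym)))
    out = out.loc[order]
    out.attrs["excluded"] = sorted(set(cn_matrix.index) - set(complete.index))
    return out.head(top) if top else out


def filter_qtls(
    qtls: Sequence[QTLRecord],
    max_ci: int = 10_000_000,
    same_qtl_overlap: float = 0.5,
) -> list[QTLRecord]:
    """High-confidence QTL filter and same-trait deduplication.

    QTLs with confidence intervals of ``max_ci`` bp or longer are dropped.
    Same-trait QTLs whose reciprocal overlap (shared bp / shorter interval)
    strictly exceeds ``same_qtl_overlap`` are treated as one QTL, represented
    by the shorter interval; a tie on length keeps the leftmost.
    """
    short = [q for q in qtls if q.length < max_ci]
    by_trait: dict[tuple[str, str], list[QTLRecord]] = {}
    for q in short:
        by_trait.setdefault((q.trait, q.chrom), []).append(q)
    out: list[QTLRecord] = []
    for group in by_trait.values():
        group = sorted(group, key=lambda q: (q.length, q.start))  # shortest first
        reps: list[QTLRecord] = []
        for q in group:
            dup = False
            for rep in reps:
                ov = overlap_bp(q.interval, rep.interval)
                if ov / min(q.length, rep.length) > same_qtl_overlap:
                    dup = True
                    break
            if not dup:
                reps.append(q)
        out.extend(reps)
    return sorted(out, key=lambda q: (q.chrom, q.start, q.trait))


def overlap_qtls(cnvrs: Sequence[CNVR], qtls: Sequence[QTLRecord]) -> dict:
    """Two-sided >= 1 bp overlap report between CNVRs and (pre-filtered) QTLs."""
    by_chrom: dict[str, list[CNVR]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append(r)
    qtl_flags = []
    hit_cnvrs: set[str] = set()
    for q in qtls:
        hits = [r for r in by_chrom.get(q.chrom, []) if overlap_bp(q.interval, r.interval) > 0]
        qtl_flags.append(bool(hits))
        hit_cnvrs.update(r.id for r in hits)
    return {
        "n_qtls": len(qtls),
        "n_qtls_overlapping": sum(qtl_flags),
        "pct_qtls_overlapping": 100.0 * sum(qtl_flags) / max(len(qtls), 1),
        "n_cnvrs_overlapping": len(hit_cnvrs),
        "pct_cnvrs_overlapping": 100.0 * len(hit_cnvrs) / max(len(cnvrs), 1),
        "qtl_flags": qtl_flags,
    }
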