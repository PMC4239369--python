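"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated with a header line; genomic coordinates in TSV
outputs are 1-based inclusive, BED output is 0-based half-open. Files written
by the simulator carry the seed in a ``#`` comment header so any artefact can
be traced back to its generating configuration.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import CNVCall
from .genome import GenomeModel
from .regions import CNVR, GeneRecord, QTLRecord


def _write_tsv(df: pd.DataFrame, path: str, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- depth tables -----------------------------------------------------------


def write_depth_table(profile, genome: GenomeModel, path: str, seed: int | None = None) -> None:
    df = profile.to_frame(genome)[["chrom", "bin_start", "bin_end", "raw", "q0_frac"]]
    df = df.rename(columns={"raw": "count"})
    _write_tsv(df, path, seed)


def read_depth_table(path: str) -> pd.DataFrame:
    return _read_tsv(path)


# -- BED-ish interval files --------------------------------------------------


def write_gaps_bed(genome: GenomeModel, path: str, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for chrom in genome.names:
            for s, e in genome.gaps.get(chrom, []):
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def read_bed_intervals(path: str) -> list[tuple[str, int, int]]:
    """BED rows as (chrom, start, end) in 1-based inclusive coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


def write_truth_bed(truth, path: str, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for ev in truth.events:
            fh.write(f"{ev.chrom}\t{ev.start - 1}\t{ev.end}\t{ev.sample}\t{ev.cn}\n")


# -- calls / CNVRs ------------------------------------------------------------


def write_calls(calls: Iterable[CNVCall], path: str, seed: int | None = None) -> None:
    rows = [
        (c.chrom, c.start, c.end, c.sample, c.type, round(c.cn, 4), c.p_value, round(c.q0, 4),
         ";".join(c.flags))
        for c in calls
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "sample", "type", "cn", "p", "q0", "flags"]
    )
    _write_tsv(df, path, seed)


def read_calls(path: str) -> list[CNVCall]:
    df = _read_tsv(path)
    return [
        CNVCall(
            sample=r["sample"], chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
            type=r["type"], cn=float(r["cn"]), p_value=float(r["p"]), q0=float(r["q0"]),
            flags=tuple(str(r.get("flags", "")).split(";")) if r.get("flags") else (),
        )
        for _, r in df.iterrows()
    ]


def write_cnvrs(cnvrs: Sequence[CNVR], path: str, seed: int | None = None) -> None:
    rows = [
        (r.id, r.chrom, r.start, r.end, r.cls, r.frequency, ";".join(sorted(r.carriers)))
        for r in cnvrs
    ]
    df = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "class", "frequency", "carriers"])
    _write_tsv(df, path, seed)


# -- annotation ---------------------------------------------------------------


def read_genes(path: str) -> list[GeneRecord]:
    """Gene table TSV: chrom, start, end, strand, symbol, transcript."""
    df = _read_tsv(path)
    return [
        GeneRecord(r["symbol"], r["transcript"], r["chrom"], int(r["start"]), int(r["end"]),
                   r.get("strand", "+"))
        for _, r in df.iterrows()
    ]


def write_genes(genes: Sequence[GeneRecord], path: str) -> None:
    df = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.strand, g.symbol, g.transcript) for g in genes],
        columns=["chrom", "start", "end", "strand", "symbol", "transcript"],
    )
    _write_tsv(df, path)


def read_qtls(path: str) -> list[QTLRecord]:
    """QTL table TSV: trait, chrom, ci_start, ci_end."""
    df = _read_tsv(path)
    return [
        QTLRecord(r["trait"], r["chrom"], int(r["ci_start"]), int(r["ci_end"]))
        for _, r in df.iterrows()
    ]


def write_qtls(qtls: Sequence[QTLRecord], path: str) -> None:
    df = pd.DataFrame(
        [(q.trait, q.chrom, q.start, q.end) for q in qtls],
        columns=["trait", "chrom", "ci_start", "ci_end"],
    )
    _write_tsv(df, path)


# -- probe / Ct tables --------------------------------------------------------


def write_probes(probes: pd.DataFrame, path: str, seed: int | None = None) -> None:
    _write_tsv(probes[["chrom", "pos", "log2ratio"]], path, seed)


def read_probes(path: str) -> pd.DataFrame:
    return _read_tsv(path)


def write_ct_table(ct: pd.DataFrame, path: str, seed: int | None = None) -> None:
    _write_tsv(ct[["sample", "region", "replicate", "Ct_target", "Ct_control"]], path, seed)


def read_ct_table(path: str) -> pd.DataFrame:
    return _read_tsv(path)


# -- FASTA and config ---------------------------------------------------------


def write_genome_fasta(genome: GenomeModel, path: str, seed: int = 0, line_width: int = 70) -> None:
    """Synthetic sequence realizing the genome's GC landscape.

    Each bin's bases are drawn i.i.d. with P(G or C) equal to the bin's GC
    fraction; gap bases are ``N``. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    bases_at = np.array(list("ATGC"), dtype="U1")
    with open(path, "w") as fh:
        for chrom, ln in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = np.empty(ln, dtype="U1")
            bs = genome.bin_size
            for i, gc in enumerate(genome.gc[chrom]):
                s, e = i * bs, min((i + 1) * bs, ln)
                draw = rng.random(e - s)
                strong = draw < gc  # G/C with prob gc
                pick = rng.integers(0, 2, e - s)
                seq[s:e] = np.where(strong, bases_at[2 + pick], bases_at[pick])
            for s, e in genome.gaps.get(chrom, []):
                seq[s - 1 : e] = "N"
            text = "".join(seq)
            for off in range(0, ln, line_width):
                fh.write(text[off : off + line_width] + "\n")


def write_config(config, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=list)


def read_config(path: str):
    from .simulate import SimulationConfig

    with open(path) as fh:
        data = json.load(fh)
    for key in ("chromosomes",):
        if key in data:
            data[key] = tuple((c, int(n)) for c, n in data[key])
    for key, val in list(data.items()):
        if isinstance(val, list):
            data[key] = tuple(val)
    return SimulationConfig(**data)
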