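"""Per-window copy-number matrices and sample clustering for heatmaps.

For a locus of interest (a gene plus flanking sequence) the copy number of
every 1 kb window is genotyped in every sample; samples are then clustered
agglomeratively with average linkage (UPGMA) on the Pearson-correlation
distance d(a, b) = 1 - r(a, b). Windows stay in genome order — only samples
are reordered.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .calling import genotype_region
from .depth import ReadDepthProfile
from .genome import GenomeModel
from .regions import GeneRecord

MAX_DISTANCE = 2.0  # d = 1 - r with r in [-1, 1]


@dataclasses.dataclass
class WindowCNMatrix:
    locus: str
    chrom: str
    window: int
    coords: list[tuple[int, int]]  # genome-ordered, 1-based inclusive
    samples: list[str]
    values: np.ndarray  # samples x windows, nan where wholly gap
    gap_columns: list[int] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.chrom}:{s}-{e}" for s, e in self.coords]
        return pd.DataFrame(self.values, index=self.samples, columns=cols)


@dataclasses.dataclass
class ClusterResult:
    samples: list[str]  # input order
    merges: list[tuple[int, int, float, int]]  # (node_a, node_b, height, size)
    leaf_order: list[str]
    zero_variance: list[str]

    def newick(self) -> str:
        n = len(self.samples)
        labels = {i: self.samples[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            la = f"{labels[a]}:{(h - heights[a]) / 2:.6g}"
            lb = f"{labels[b]}:{(h - heights[b]) / 2:.6g}"
            labels[n + k] = f"({la},{lb})"
            heights[n + k] = h
        return labels[n + len(self.merges) - 1] + ";" if self.merges else self.samples[0] + ";"


def window_cn_matrix(
    profiles: Mapping[str, ReadDepthProfile],
    gene: GeneRecord,
    genome: GenomeModel,
    flank: int = 30_000,
    window: int = 1_000,
) -> WindowCNMatrix:
    """Copy number of every window across ``gene`` +- ``flank`` in every sample.

    The locus is clipped at chromosome ends; windows run from the clipped
    start in genome order, the last one possibly partial. Wholly-gap windows
    are nan for every sample and flagged in ``gap_columns``.
    """
    for sample, prof in profiles.items():
        if gene.chrom not in prof.corrected:
            raise KeyError(f"chromosome {gene.chrom} absent from profile of {sample}")
    lo = max(1, gene.start - flank)
    hi = min(genome.length(gene.chrom), gene.end + flank)
    coords = [(s, min(s + window - 1, hi)) for s in range(lo, hi + 1, window)]
    samples = list(profiles)
    values = np.full((len(samples), len(coords)), np.nan)
    for i, sample in enumerate(samples):
        for j, (s, e) in enumerate(coords):
            values[i, j] = genotype_region(profiles[sample], (gene.chrom, s, e), genome)
    gap_cols = [j for j in range(len(coords)) if np.isnan(values[:, j]).all()]
    return WindowCNMatrix(gene.symbol, gene.chrom, window, coords, samples, values, gap_cols)


def pearson_distance_matrix(matrix: WindowCNMatrix) -> tuple[np.ndarray, list[str]]:
    """Pairwise d = 1 - Pearson r over non-gap windows; zero-variance rows get d = 2."""
    vals = np.delete(matrix.values, matrix.gap_columns, axis=1)
    n = len(matrix.samples)
    sd = vals.std(axis=1)
    flat = [matrix.samples[i] for i in range(n) if sd[i] < 1e-12]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] < 1e-12 or sd[j] < 1e-12:
                dij = MAX_DISTANCE
            else:
                r = float(np.corrcoef(vals[i], vals[j])[0, 1])
                dij = 1.0 - r
            d[i, j] = d[j, i] = dij
    return d, flat


def cluster_samples(matrix: WindowCNMatrix) -> ClusterResult:
    """Agglomerative average-linkage (UPGMA) clustering of the samples.

    Distance is 1 - Pearson r of the CN rows. On equal merge heights the
    pair with the lowest (index_a, index_b) merges first, making the merge
    tree and leaf order deterministic. Leaf order follows the merge tree
    with the lower-index branch kept left.
    """
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    d, flat = pearson_distance_matrix(matrix)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    alive = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(alive) > 1:
        best = min(
            ((dist[(min(a, b), max(a, b))], a, b) for ai, a in enumerate(alive) for b in alive[ai + 1 :]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, a, b = best
        merges.append((a, b, h, len(members[a]) + len(members[b])))
        members[next_id] = members[a] + members[b]
        leaves[next_id] = leaves[a] + leaves[b]
        alive = [k for k in alive if k not in (a, b)]
        for k in alive:
            # unweighted average linkage: mean pairwise distance between members
            na, nb = len(members[a]), len(members[b])
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            dist[(min(next_id, k), max(next_id, k))] = (na * da + nb * db) / (na + nb)
        alive.append(next_id)
        next_id += 1
    order = [matrix.samples[i] for i in leaves[next_id - 1]]
    return ClusterResult(list(matrix.samples), merges, order, flat)


def render_heatmap(
    matrix: WindowCNMatrix,
    clustering: ClusterResult | None,
    image_path: str,
    text_path: str | None = None,
    cn_ceiling: float = 8.0,
):
    """Write a heatmap image plus a diffable text dump of the matrix.

    Sample rows follow the dendrogram leaf order (input order when
    ``clustering`` is None, e.g. a single-sample matrix); windows stay in
    genome order. The colour scale is linear from 0 to ``cn_ceiling`` copies.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = matrix.to_frame()
    if clustering is not None:
        frame = frame.loc[clustering.leaf_order]
    if text_path:
        frame.to_csv(text_path, sep="\t", float_format="%.4f")
    fig, ax = plt.subplots(
        figsize=(max(4.0, len(matrix.coords) * 0.04), max(2.0, len(frame) * 0.3))
    )
    im = ax.imshow(
        frame.to_numpy(), aspect="auto", interpolation="nearest",
        vmin=0.0, vmax=cn_ceiling, cmap="RdBu_r",
    )
    ax.set_yticks(range(len(frame)), frame.index)
    ax.set_xticks([])
    ax.set_xlabel(f"{matrix.chrom} ({matrix.window} bp windows, genome order)")
    ax.set_title(matrix.locus)
    fig.colorbar(im, ax=ax, label="copy number")
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)
    return frame
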