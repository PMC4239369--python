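"""Quality assessment of read-depth CNV predictions.

Three independent procedures:

* **digital aCGH** — for a (test, reference) sample pair, split the two
  samples' CNV calls into non-overlapping subsegments, genotype each
  subsegment in both samples and form ``log2(CN_test / CN_ref)``; compare
  against the mean hybridization-array probe log2 ratio over the same
  segments by Pearson correlation and simple linear regression.
* **qPCR** — estimate absolute copy number from Ct tables with the
  control-normalized ddCt method, ``CN = ploidy_ref * 2^(-ddCt)`` (the
  classic ``2^(1-ddCt)`` for a diploid baseline), and score predictions by
  positive predictive value and false-negative rate.
* **neutral-region QC** — genotype all autosomal windows clear of predicted
  CNVs and gaps; their copy numbers should sit near 2.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CNVCall, genotype_region, genotype_windows
from .depth import ReadDepthProfile
from .genome import GenomeModel
from .intervals import overlap_bp
from .simulate import PSEUDO_CN

# qPCR status cuts on the diploid scale: >= 2.5 copies counts as a gain,
# <= 1.5 as a loss; halved on the haploid female Z chromosome.
GAIN_CUT = 2.5
LOSS_CUT = 1.5


@dataclasses.dataclass(frozen=True)
class PairSegment:
    chrom: str
    start: int
    end: int
    origin: str  # "both" | "test" | "ref" | "test_unique" | "ref_unique"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclasses.dataclass
class PairwiseSegmentSet:
    test_sample: str
    ref_sample: str
    segments: list[PairSegment]


def split_pairwise_segments(
    calls_test: Sequence[CNVCall],
    calls_ref: Sequence[CNVCall],
    min_len: int = 1_000,
) -> PairwiseSegmentSet:
    """Partition two samples' calls into disjoint segments.

    Overlapping call pairs are cut at every call boundary into non-overlapping
    subsegments (origin ``both``/``test``/``ref`` by which sample's calls
    cover the piece); calls unique to one sample are kept whole. Segments of
    ``min_len`` bp or shorter are discarded.
    """
    t_sample = calls_test[0].sample if calls_test else "test"
    r_sample = calls_ref[0].sample if calls_ref else "ref"
    chroms = sorted({c.chrom for c in list(calls_test) + list(calls_ref)})
    segments: list[PairSegment] = []
    for chrom in chroms:
        t_ivs = sorted(c.interval for c in calls_test if c.chrom == chrom)
        r_ivs = sorted(c.interval for c in calls_ref if c.chrom == chrom)
        t_hit = [any(overlap_bp(a, b) for b in r_ivs) for a in t_ivs]
        r_hit = [any(overlap_bp(b, a) for a in t_ivs) for b in r_ivs]
        for iv, hit in zip(t_ivs, t_hit):
            if not hit and iv[1] - iv[0] + 1 > min_len:
                segments.append(PairSegment(chrom, iv[0], iv[1], "test_unique"))
        for iv, hit in zip(r_ivs, r_hit):
            if not hit and iv[1] - iv[0] + 1 > min_len:
                segments.append(PairSegment(chrom, iv[0], iv[1], "ref_unique"))
        overlapping = [iv for iv, h in zip(t_ivs, t_hit) if h] + [
            iv for iv, h in zip(r_ivs, r_hit) if h
        ]
        for comp in _connected_components(overlapping):
            cuts = sorted({s for s, _ in comp} | {e + 1 for _, e in comp})
            for cs, ce in zip(cuts[:-1], cuts[1:]):
                piece = (cs, ce - 1)
                in_t = any(overlap_bp(piece, iv) for iv in t_ivs)
                in_r = any(overlap_bp(piece, iv) for iv in r_ivs)
                if not (in_t or in_r):
                    continue
                origin = "both" if in_t and in_r else ("test" if in_t else "ref")
                if piece[1] - piece[0] + 1 > min_len:
                    segments.append(PairSegment(chrom, piece[0], piece[1], origin))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return PairwiseSegmentSet(t_sample, r_sample, segments)


def _connected_components(ivs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    comps: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    end = -1
    for iv in sorted(ivs):
        if cur and iv[0] <= end:
            cur.append(iv)
            end = max(end, iv[1])
        else:
            if cur:
                comps.append(cur)
            cur = [iv]
            end = iv[1]
    if cur:
        comps.append(cur)
    return comps


def digital_acgh(
    profile_test: ReadDepthProfile,
    profile_ref: ReadDepthProfile,
    segments: PairwiseSegmentSet | Sequence[PairSegment],
    genome: GenomeModel,
) -> pd.DataFrame:
    """Per-segment log2 CN ratio of test vs reference from read depth.

    Copy numbers at or below zero are floored at ``PSEUDO_CN`` (0.5 copies)
    before taking the ratio. Segments wholly inside gaps in either sample are
    dropped; the returned frame's ``attrs['dropped']`` lists them.
    """
    segs = segments.segments if isinstance(segments, PairwiseSegmentSet) else list(segments)
    rows, dropped = [], []
    for seg in segs:
        cn_t = genotype_region(profile_test, seg.region, genome)
        cn_r = genotype_region(profile_ref, seg.region, genome)
        if math.isnan(cn_t) or math.isnan(cn_r):
            dropped.append(seg.region)
            continue
        ratio = math.log2(max(cn_t, PSEUDO_CN) / max(cn_r, PSEUDO_CN))
        rows.append((seg.chrom, seg.start, seg.end, seg.origin, cn_t, cn_r, ratio))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "origin", "cn_test", "cn_ref", "log2ratio"]
    )
    df.attrs["dropped"] = dropped
    return df


def probe_segment_mean(probes: pd.DataFrame, segment: tuple[str, int, int]) -> float:
    """Mean probe log2 ratio over one segment (nan when no probe falls inside)."""
    chrom, start, end = segment
    sel = probes[
        (probes["chrom"] == chrom) & (probes["pos"] >= start) & (probes["pos"] <= end)
    ]
    return float(sel["log2ratio"].mean()) if len(sel) else float("nan")


def correlate_validation(
    digital: Sequence[float], experimental: Sequence[float]
) -> dict:
    """Pearson r and least-squares fit between paired digital and probe values.

    Pairs with an undefined value on either side are excluded. Also reports
    the mean of the experimental values (a global offset there flags array
    bias). Requires >= 3 complete pairs; zero variance on either side yields
    ``r = nan`` with a flag.
    """
    x = np.asarray(digital, dtype=float)
    y = np.asarray(experimental, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired segments, got {x.size}")
    out = {"n": int(x.size), "mean_experimental": float(y.mean())}
    if x.std() == 0 or y.std() == 0:
        out.update(r=float("nan"), slope=float("nan"), intercept=float("nan"),
                   degenerate=True)
        return out
    fit = stats.linregress(x, y)
    out.update(
        r=float(stats.pearsonr(x, y).statistic),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        degenerate=False,
    )
    return out


# ---------------------------------------------------------------------------
# qPCR


def qpcr_copy_number(
    ct_table: pd.DataFrame,
    region: str,
    reference_sample: str,
    ploidy_ref: int = 2,
    efficiency: float = 2.0,
    expected_replicates: int | None = None,
) -> pd.Series:
    """Per-sample absolute copy number from a Ct table by the ddCt method.

    dCt = mean over replicates of (Ct_target - Ct_control); ddCt = dCt_test -
    dCt_reference; CN = ploidy_ref * eff^(-ddCt). With the diploid baseline
    this is the textbook ``2^(1 - ddCt)``; on the female Z chromosome
    ``ploidy_ref = 1`` gives ``2^(-ddCt)``. Samples with missing replicates
    are excluded and listed in ``result.attrs['excluded']``.
    """
    sub = ct_table[ct_table["region"] == region]
    if reference_sample not in set(sub["sample"]):
        raise ValueError(f"reference sample {reference_sample!r} missing for region {region!r}")
    dct = {}
    excluded = []
    for sample, grp in sub.groupby("sample"):
        if expected_replicates is not None and len(grp) < expected_replicates:
            excluded.append(sample)
            continue
        dct[sample] = float((grp["Ct_target"] - grp["Ct_control"]).mean())
    ddct = {s: v - dct[reference_sample] for s, v in dct.items()}
    cn = pd.Series(
        {s: ploidy_ref * efficiency ** (-d) for s, d in ddct.items()}, name="cn"
    ).sort_index()
    cn.attrs["excluded"] = excluded
    return cn


def qpcr_status(cn: float, ploidy: int = 2) -> str:
    """Classify a qPCR copy number as gain / loss / normal at the standard cuts."""
    scale = ploidy / 2.0
    if cn >= GAIN_CUT * scale:
        return "gain"
    if cn <= LOSS_CUT * scale:
        return "loss"
    return "normal"


def confirmation_rates(
    predictions: Mapping[str, Mapping[str, str | None]],
    qpcr_cn: Mapping[str, Mapping[str, float]],
    ploidy: Mapping[str, int] | None = None,
) -> dict:
    """Positive predictive value and false-negative rate of CNV predictions.

    ``predictions[region][sample]`` is ``"duplication"``/``"deletion"`` for a
    predicted carrier or ``None`` for a predicted-negative sample;
    ``qpcr_cn[region][sample]`` is the measured copy number. A positive is
    confirmed when its qPCR status matches the predicted direction; a
    negative is a false negative when its qPCR status is not ``normal``.
    Returns per-region rates, their unweighted averages, and sample-pooled
    rates.
    """
    rows = []
    pooled = {"tp": 0, "pos": 0, "fn": 0, "neg": 0}
    for region, pred in predictions.items():
        pl = (ploidy or {}).get(region, 2)
        tp = pos = fn = neg = 0
        for sample, kind in pred.items():
            cn = qpcr_cn[region].get(sample)
            if cn is None:
                continue
            status = qpcr_status(cn, pl)
            if kind is not None:
                pos += 1
                want = "gain" if kind == "duplication" else "loss"
                tp += status == want
            else:
                neg += 1
                fn += status != "normal"
        rows.append(
            (
                region,
                pos,
                100.0 * tp / pos if pos else float("nan"),
                neg,
                100.0 * fn / neg if neg else float("nan"),
            )
        )
        pooled["tp"] += tp
        pooled["pos"] += pos
        pooled["fn"] += fn
        pooled["neg"] += neg
    table = pd.DataFrame(rows, columns=["region", "n_positive", "ppv_pct", "n_negative", "fnr_pct"])
    ppv_vals = table["ppv_pct"].dropna()
    fnr_vals = table["fnr_pct"].dropna()
    return {
        "per_region": table,
        "ppv_pct_mean": float(ppv_vals.mean()) if len(ppv_vals) else float("nan"),
        "fnr_pct_mean": float(fnr_vals.mean()) if len(fnr_vals) else float("nan"),
        "ppv_pct_pooled": 100.0 * pooled["tp"] / pooled["pos"] if pooled["pos"] else float("nan"),
        "fnr_pct_pooled": 100.0 * pooled["fn"] / pooled["neg"] if pooled["neg"] else float("nan"),
        "regions_without_positives": table.loc[table["n_positive"] == 0, "region"].tolist(),
    }


# ---------------------------------------------------------------------------
# neutral-region QC


def neutral_qc_report(
    profiles: Mapping[str, ReadDepthProfile],
    calls: Mapping[str, Sequence[CNVCall]],
    genome: GenomeModel,
    window: int = 5_000,
) -> pd.DataFrame:
    """Per-sample mean and STDEV of copy number in CNV-free autosomal windows.

    Wraps :func:`genotype_windows` with each sample's own calls (plus gaps)
    excluded. Samples whose windows are all excluded are absent from the
    table. The cohort grand mean and STDEV sit in ``attrs``.
    """
    rows = []
    for sample, profile in profiles.items():
        exclude = [(c.chrom, c.start, c.end) for c in calls.get(sample, [])]
        df, mean, stdev = genotype_windows(profile, genome, window, exclude)
        if df.empty:
            continue
        rows.append((sample, mean, stdev, len(df)))
    out = pd.DataFrame(rows, columns=["sample", "mean_cn", "stdev_cn", "n_windows"])
    if len(out):
        out.attrs["grand_mean"] = float(out["mean_cn"].mean())
        out.attrs["grand_stdev"] = float(out["mean_cn"].std(ddof=1)) if len(out) > 1 else 0.0
    return out
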