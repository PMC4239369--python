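"""Parameter-recovery evaluation of the caller against simulator truth."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .calling import CNVCall, call_cnvs
from .depth import ReadDepthProfile
from .genome import GenomeModel
from .intervals import overlap_bp
from .simulate import TruthSet


def cohort_calls(
    profiles: Mapping[str, ReadDepthProfile], genome: GenomeModel, **kwargs
) -> dict[str, list[CNVCall]]:
    return {s: call_cnvs(p, genome, **kwargs)[0] for s, p in profiles.items()}


def recovery_metrics(
    truth: TruthSet,
    calls: Mapping[str, Sequence[CNVCall]],
    genome: GenomeModel,
    min_event_len: int = 5_000,
    boundary_tol_bins: int = 2,
) -> dict:
    """Score called CNVs against embedded events.

    An event counts as *detected* when one call covers more than half of it;
    its boundary is *precise* when both edges of that call sit within
    ``boundary_tol_bins`` bins of the true breakpoints. The CN error is the
    absolute difference between the call's copy-number estimate and the true
    integer copy number. False positives are calls overlapping no event at
    all (events below ``min_event_len`` still shield their calls).
    """
    bs = genome.bin_size
    n_events = n_detected = n_precise = 0
    cn_errors: list[float] = []
    n_fp = 0
    for sample in truth.samples:
        sample_calls = list(calls.get(sample, []))
        evs = truth.events_for(sample)
        for ev in evs:
            if ev.length < min_event_len:
                continue
            n_events += 1
            hits = [
                c
                for c in sample_calls
                if c.chrom == ev.chrom
                and overlap_bp((c.start, c.end), (ev.start, ev.end)) > 0.5 * ev.length
            ]
            if not hits:
                continue
            best = max(
                hits, key=lambda c: overlap_bp((c.start, c.end), (ev.start, ev.end))
            )
            n_detected += 1
            cn_errors.append(abs(best.cn - ev.cn))
            err = max(abs(best.start - ev.start), abs(best.end - ev.end)) / bs
            if err <= boundary_tol_bins:
                n_precise += 1
        for c in sample_calls:
            if not any(
                c.chrom == e.chrom and overlap_bp((c.start, c.end), (e.start, e.end)) > 0
                for e in evs
            ):
                n_fp += 1
    return {
        "n_events": n_events,
        "n_detected": n_detected,
        "recall_pct": 100.0 * n_detected / n_events if n_events else float("nan"),
        "n_boundary_precise": n_precise,
        "boundary_precise_pct": 100.0 * n_precise / n_events if n_events else float("nan"),
        "mean_abs_cn_error": float(np.mean(cn_errors)) if cn_errors else float("nan"),
        "n_false_positive_calls": n_fp,
    }
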