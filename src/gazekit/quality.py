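"""Data-quality metrics and cross-algorithm agreement statistics.

Two sample-level metrics characterize a recording: *data loss* (the
proportion of samples without a valid gaze coordinate — interpolated samples
still count as lost, since the metric describes what the tracker recorded)
and *precision*, measured as the sample-to-sample root-mean-square
displacement (RMSD) in degrees.

Agreement between two classifiers is summarized by the relative timing
offset (RTO, mean of matched onset/offset differences) and relative timing
deviation (RTD, their standard deviation), computed over fixations matched
one-to-one within a temporal margin (default 15 ms).  The sign convention is
``comparison − reference``: positive RTO_onset means the comparison stream
starts its fixations later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventSet
from .io import GazeRecording, InputError

__all__ = ["ComparisonStats", "proportion_data_loss", "rmsd_precision",
           "compare_event_streams", "summarize_algorithms", "fixation_f1"]


@dataclass
class ComparisonStats:
    """RTO/RTD agreement summary between two event streams.

    Differences are ``b − a`` (comparison minus reference).  RTD uses the
    n−1 denominator and is NaN when fewer than two fixations matched.
    """

    rto_onset_ms: float
    rtd_onset_ms: float
    rto_offset_ms: float
    rtd_offset_ms: float
    n_matched: int
    n_unmatched_a: int
    n_unmatched_b: int
    margin_ms: float


def proportion_data_loss(rec: GazeRecording) -> float:
    """Proportion of samples missing in the original recording.

    Interpolation does not change this metric: interpolated samples carry a
    flag and still count as originally missing.
    """
    if rec.n == 0:
        raise InputError("empty recording")
    return float(np.mean(rec.missing))


def rmsd_precision(rec: GazeRecording,
                   span: tuple[float, float] | None = None) -> float:
    """Sample-to-sample RMS displacement (deg) over consecutive valid pairs.

    ``span`` restricts the computation to ``span[0] <= t < span[1]``.
    Raises when the span holds no consecutive valid pair.
    """
    sel = np.ones(rec.n, dtype=bool)
    if span is not None:
        sel = (rec.t >= span[0]) & (rec.t < span[1])
    idx = np.nonzero(sel)[0]
    if idx.size < 2:
        raise InputError("need at least 2 samples in span")
    x, y, valid = rec.x[idx], rec.y[idx], rec.valid[idx]
    contiguous = np.diff(idx) == 1
    ok = valid[:-1] & valid[1:] & contiguous
    if not ok.any():
        raise InputError("no consecutive valid sample pair in span")
    dx, dy = np.diff(x)[ok], np.diff(y)[ok]
    return float(np.sqrt(np.mean(dx * dx + dy * dy)))


def compare_event_streams(a: EventSet, b: EventSet,
                          margin_ms: float = 15.0) -> ComparisonStats:
    """Match fixations of ``b`` to fixations of ``a`` and summarize timing.

    For each fixation in ``a`` (chronological), its match is the first unused
    fixation of ``b`` whose onset is ≥ ``a.onset − margin`` and offset is
    ≤ ``a.offset + margin``.  Matching is one-to-one: a matched fixation of
    ``b`` is consumed and cannot match again.
    """
    fa = a.fixations()
    fb = b.fixations()
    used = np.zeros(len(fb), dtype=bool)
    d_on, d_off = [], []
    for ev in fa:
        for j, cand in enumerate(fb):
            if used[j]:
                continue
            if (cand.onset_ms >= ev.onset_ms - margin_ms
                    and cand.offset_ms <= ev.offset_ms + margin_ms):
                used[j] = True
                d_on.append(cand.onset_ms - ev.onset_ms)
                d_off.append(cand.offset_ms - ev.offset_ms)
                break
    n = len(d_on)
    arr_on, arr_off = np.asarray(d_on), np.asarray(d_off)
    return ComparisonStats(
        rto_onset_ms=float(np.mean(arr_on)) if n else float("nan"),
        rtd_onset_ms=float(np.std(arr_on, ddof=1)) if n >= 2 else float("nan"),
        rto_offset_ms=float(np.mean(arr_off)) if n else float("nan"),
        rtd_offset_ms=float(np.std(arr_off, ddof=1)) if n >= 2 else float("nan"),
        n_matched=n,
        n_unmatched_a=len(fa) - n,
        n_unmatched_b=len(fb) - n,
        margin_ms=margin_ms,
    )


def summarize_algorithms(sets, rec: GazeRecording | None = None) -> pd.DataFrame:
    """Descriptive fixation statistics per algorithm.

    Returns one row per event set: fixation count, mean/sd duration, mean
    within-fixation RMSD, mean proportion of missing samples, and total
    fixation time (ms).  Undefined means (empty sets) are NaN.
    """
    if isinstance(sets, EventSet):
        sets = [sets]
    rows = []
    for es in sets:
        fx = es.fixations()
        durs = np.array([f.duration_ms for f in fx])
        rmsd = np.array([f.rmsd_deg for f in fx])
        miss = np.array([f.prop_missing for f in fx])
        rows.append({
            "algorithm": es.algorithm or "unknown",
            "n_fixations": len(fx),
            "mean_duration_ms": float(np.mean(durs)) if len(fx) else float("nan"),
            "sd_duration_ms": (float(np.std(durs, ddof=1)) if len(fx) >= 2
                               else float("nan")),
            "mean_rmsd_deg": (float(np.nanmean(rmsd)) if len(fx)
                              and np.isfinite(rmsd).any() else float("nan")),
            "mean_prop_missing": (float(np.nanmean(miss)) if len(fx)
                                  and np.isfinite(miss).any() else float("nan")),
            "total_fixation_time_ms": float(np.sum(durs)) if len(fx) else 0.0,
        })
    return pd.DataFrame(rows)


def fixation_f1(truth: EventSet, detected: EventSet,
                min_overlap: float = 0.5) -> float:
    """F1 score of detected fixations against ground-truth fixations.

    Greedy chronological one-to-one matching: a detected fixation matches a
    truth fixation when their temporal overlap covers at least
    ``min_overlap`` of the shorter of the two.  Returns 0 when either set is
    empty (and 1 only if both are).
    """
    ft = truth.fixations()
    fd = detected.fixations()
    if not ft and not fd:
        return 1.0
    if not ft or not fd:
        return 0.0
    used = np.zeros(len(fd), dtype=bool)
    tp = 0
    for ev in ft:
        for j, cand in enumerate(fd):
            if used[j]:
                continue
            ov = (min(ev.offset_ms, cand.offset_ms)
                  - max(ev.onset_ms, cand.onset_ms))
            shorter = min(ev.duration_ms, cand.duration_ms)
            if ov > 0 and ov >= min_overlap * shorter:
                used[j] = True
                tp += 1
                break
    precision = tp / len(fd)
    recall = tp / len(ft)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
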