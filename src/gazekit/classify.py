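"""Fixation/saccade event-classification algorithms.

Four classifiers are provided, spanning the families in common use:

* **I-VT** — identification by velocity threshold: samples whose angular
  speed exceeds a fixed cutoff (default 30°/s) are saccadic; the periods
  between saccades are fixations.
* **I-DT** — identification by dispersion threshold: a fixation grows sample
  by sample while every incoming valid sample stays within a radius (default
  1°) of the running centroid.
* **Adaptive velocity threshold** — the peak-saccade cutoff is iterated to a
  fixed point of ``mean + λ·sd`` over sub-threshold velocities, adapting to
  the noise level; saccade on/offsets are then found by walking out from each
  velocity peak against locally noise-calibrated thresholds.
* **I2MC** — identification by two-means clustering: sliding 200-ms windows
  (also over block-downsampled copies of the data) are split into two
  clusters; samples where the cluster assignment switches accumulate weight,
  and fixations are the periods between high-weight transitions.  Designed to
  stay robust under heavy noise and data loss.

All classifiers consume a recording in degrees and return an
:class:`~gazekit.events.EventSet`.  Every fixation they emit satisfies the
minimum-duration rule and the missing-samples rule (fixations consisting
mostly of invalid samples are artifacts of gaps, not gaze, and are dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .events import Event, EventSet, FIXATION, SACCADE, event_from_samples
from .io import GazeRecording, InputError
from .preprocess import downsample_by_factor
from .velocity import VelocityTrace, compute_velocity

__all__ = [
    "IVTParams", "IDTParams", "AdaptiveParams", "I2MCParams",
    "classify_ivt", "classify_idt", "classify_adaptive", "classify_i2mc",
    "CLASSIFIERS",
]


# ---------------------------------------------------------------------------
# parameter blocks

@dataclass
class IVTParams:
    velocity_threshold_dps: float = 30.0
    min_fixation_ms: float = 60.0
    min_saccade_ms: float = 10.0
    missing_samples_threshold: float = 0.5
    merge_dist_deg: float | None = 0.5
    merge_gap_ms: float | None = 75.0
    velocity_smooth_window_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.velocity_threshold_dps <= 0:
            raise ValueError("velocity_threshold_dps must be > 0")
        if self.min_fixation_ms < 0 or self.min_saccade_ms < 0:
            raise ValueError("durations must be >= 0")


@dataclass
class IDTParams:
    dispersion_threshold_deg: float = 1.0
    min_fixation_ms: float = 60.0
    missing_samples_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.dispersion_threshold_deg <= 0:
            raise ValueError("dispersion_threshold_deg must be > 0")


@dataclass
class AdaptiveParams:
    initial_peak_threshold_dps: float = 200.0
    lam: float = 6.0
    convergence_tol_dps: float = 1.0
    min_fixation_ms: float = 40.0
    min_saccade_ms: float = 12.0
    onset_lambda: float = 3.0
    offset_weight_alpha: float = 0.7
    noise_window_ms: float = 40.0
    missing_samples_threshold: float = 0.5
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.initial_peak_threshold_dps <= 0:
            raise ValueError("lambda and the initial peak threshold must be > 0")
        if not 0.0 <= self.offset_weight_alpha <= 1.0:
            raise ValueError("offset_weight_alpha must lie in [0, 1]")


@dataclass
class I2MCParams:
    window_ms: float = 200.0
    step_ms: float = 20.0
    downsample_factors: tuple[int, ...] = (2, 5, 10)
    weight_cutoff_sd: float = 2.0
    merge_dist_deg: float | None = 0.7
    merge_gap_ms: float | None = 30.0
    min_fixation_ms: float = 40.0
    min_valid_prop_window: float = 0.5
    missing_samples_threshold: float = 0.5
    edge_refine_sd: float | None = 3.0

    def __post_init__(self) -> None:
        if not self.window_ms > self.step_ms > 0:
            raise ValueError("require window_ms > step_ms > 0")
        if any(int(f) != f or f < 2 for f in self.downsample_factors):
            raise ValueError("downsample factors must be integers >= 2")
        if self.weight_cutoff_sd <= 0:
            raise ValueError("weight_cutoff_sd must be > 0")


# ---------------------------------------------------------------------------
# shared helpers

def _runs_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _segment_duration(rec: GazeRecording, i0: int, i1: int) -> float:
    off = rec.t[i1 + 1] if i1 + 1 < rec.n else rec.t[i1] + rec.median_dt_ms()
    return float(off - rec.t[i0])


def _complement_segments(n: int, runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Index segments not covered by `runs` (which are sorted, disjoint)."""
    segs = []
    pos = 0
    for a, b in runs:
        if a > pos:
            segs.append((pos, a - 1))
        pos = b + 1
    if pos <= n - 1:
        segs.append((pos, n - 1))
    return segs


def _build_events(rec: GazeRecording, sac_runs: list[tuple[int, int]],
                  algorithm: str, params, v: np.ndarray | None,
                  min_fixation_ms: float, missing_threshold: float,
                  min_saccade_ms: float = 0.0,
                  merge_dist_deg: float | None = None,
                  merge_gap_ms: float | None = None) -> EventSet:
    """Turn saccade index runs into a full EventSet with filtered fixations."""
    n = rec.n
    kept_sacs = [(a, b) for a, b in sac_runs
                 if _segment_duration(rec, a, b) >= min_saccade_ms]
    events: list[Event] = []
    for a, b in kept_sacs:
        events.append(event_from_samples(
            rec, a, b, SACCADE, algorithm, velocity=v,
            edge_truncated=(a == 0 or b == n - 1)))
    for a, b in _complement_segments(n, kept_sacs):
        if _segment_duration(rec, a, b) < min_fixation_ms:
            continue
        # the missing-samples rule guards against fixations "detected" inside
        # gaps: it counts samples still invalid after preprocessing, whereas
        # prop_missing reports pre-interpolation missingness for QC
        if np.mean(~rec.valid[a:b + 1]) > missing_threshold:
            continue
        events.append(event_from_samples(rec, a, b, FIXATION, algorithm,
                                         edge_truncated=(a == 0 or b == n - 1)))
    out = EventSet(events=events, algorithm=algorithm,
                   params=_params_dict(params), recording=rec)
    if merge_dist_deg is not None and merge_gap_ms is not None:
        from .postprocess import merge_adjacent_fixations
        out = merge_adjacent_fixations(out, merge_dist_deg, merge_gap_ms)
    return out


def _params_dict(params) -> dict:
    d = asdict(params)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


# ---------------------------------------------------------------------------
# I-VT

def classify_ivt(rec: GazeRecording, params: IVTParams | None = None) -> EventSet:
    """Velocity-threshold classification.

    Samples with speed above ``velocity_threshold_dps`` are saccadic (an
    undefined velocity is never saccadic and breaks saccade runs); maximal
    saccade runs shorter than ``min_saccade_ms`` dissolve into the
    surrounding fixation context.  Fixations are the remaining intervals,
    kept when they last at least ``min_fixation_ms`` and contain at most
    ``missing_samples_threshold`` originally-missing samples; adjacent
    fixations are optionally merged.
    """
    params = params or IVTParams()
    vel = compute_velocity(rec, params.velocity_smooth_window_ms)
    sac_mask = ivt_saccade_mask(vel, params.velocity_threshold_dps)
    runs = _runs_true(sac_mask)
    return _build_events(rec, runs, "ivt", params, vel.v,
                         params.min_fixation_ms,
                         params.missing_samples_threshold,
                         params.min_saccade_ms,
                         params.merge_dist_deg, params.merge_gap_ms)


def ivt_saccade_mask(vel: VelocityTrace, threshold_dps: float) -> np.ndarray:
    """Per-sample saccade labels before any duration filtering or merging.

    Exactly ``{i : v[i] > threshold}``; NaN velocities are never saccadic.
    """
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(vel.v, nan=-np.inf) > threshold_dps


# ---------------------------------------------------------------------------
# I-DT

def classify_idt(rec: GazeRecording, params: IDTParams | None = None) -> EventSet:
    """Dispersion-threshold classification.

    Greedy left-to-right scan: a candidate fixation grows while every
    incoming valid sample lies within ``dispersion_threshold_deg`` of the
    running centroid of the valid samples included so far; invalid samples
    are tolerated inside a candidate (up to the missing-samples rule).  On a
    violation the candidate is emitted (if long enough) and the scan restarts
    at the violating sample.  Intervals between fixations are reported as
    saccades without velocity metrics.
    """
    params = params or IDTParams()
    if rec.unit != "deg":
        raise InputError("classify_idt requires a recording in degrees")
    n = rec.n
    x, y, valid = rec.x, rec.y, rec.valid
    fixations: list[tuple[int, int]] = []

    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        # start a candidate at the next valid sample
        sum_x, sum_y, cnt = x[i], y[i], 1
        start = i
        last_valid = i
        j = i + 1
        while j < n:
            if not valid[j]:
                j += 1
                continue
            cx, cy = sum_x / cnt, sum_y / cnt
            if np.hypot(x[j] - cx, y[j] - cy) > params.dispersion_threshold_deg:
                break
            sum_x += x[j]
            sum_y += y[j]
            cnt += 1
            last_valid = j
            j += 1
        if _segment_duration(rec, start, last_valid) >= params.min_fixation_ms:
            fixations.append((start, last_valid))
        i = j if j > i else i + 1

    events: list[Event] = []
    for a, b in fixations:
        if np.mean(~valid[a:b + 1]) > params.missing_samples_threshold:
            continue
        events.append(event_from_samples(rec, a, b, FIXATION, "idt",
                                         edge_truncated=(a == 0 or b == n - 1)))
    # inter-fixation intervals as saccades (no velocity metrics)
    fix_kept = [(e.first_sample, e.last_sample) for e in events]
    for a, b in _complement_segments(n, sorted(fix_kept)):
        try:
            events.append(event_from_samples(
                rec, a, b, SACCADE, "idt",
                edge_truncated=(a == 0 or b == n - 1)))
        except ValueError:
            pass
    return EventSet(events=events, algorithm="idt",
                    params=_params_dict(params), recording=rec)


# ---------------------------------------------------------------------------
# adaptive velocity threshold

def adaptive_peak_threshold(v: np.ndarray, pt0: float, lam: float,
                            tol: float, max_iterations: int = 100
                            ) -> tuple[float, int]:
    """Fixed-point iteration for the peak-saccade velocity threshold.

    PT_{k+1} = mean(v | v ≤ PT_k) + λ·sd(v | v ≤ PT_k), iterated until the
    change falls below ``tol``.  The sub-threshold set is inclusive (v ≤ PT)
    so a zero-variance trace converges in one step.  Returns (PT, iterations).
    """
    v = np.asarray(v, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise InputError("no defined velocities for threshold adaptation")
    pt = float(pt0)
    for k in range(1, max_iterations + 1):
        sub = v[v <= pt]
        if sub.size == 0:
            warnings.warn("peak-threshold update emptied the sub-threshold "
                          "set; keeping previous threshold", RuntimeWarning)
            return pt, k - 1
        sd = float(np.std(sub, ddof=1)) if sub.size > 1 else 0.0
        new = float(np.mean(sub)) + lam * sd
        if abs(new - pt) < tol:
            return new, k
        pt = new
    raise RuntimeError(
        f"peak-threshold iteration did not converge in {max_iterations} "
        f"steps (last values {pt:.6g}, {new:.6g})")


def _local_stats(v: np.ndarray, t: np.ndarray, lo_ms: float, hi_ms: float,
                 fallback: tuple[float, float]) -> tuple[float, float]:
    sel = (t >= lo_ms) & (t < hi_ms) & np.isfinite(v)
    vv = v[sel]
    if vv.size < 2:
        return fallback
    return float(np.mean(vv)), float(np.std(vv, ddof=1))


def classify_adaptive(rec: GazeRecording,
                      params: AdaptiveParams | None = None) -> EventSet:
    """Noise-adaptive saccade detection.

    The peak velocity threshold PT is iterated to the fixed point of
    ``mean + λ·sd`` over velocities ≤ PT.  Each maximal run with v > PT is a
    saccade peak; its onset is found by walking backwards until the speed
    drops below ``μ + onset_lambda·σ`` of the noise window preceding the
    peak, and its offset by walking forwards until the speed drops below a
    weighted mix (``offset_weight_alpha``) of the onset threshold and the
    post-saccade noise threshold.  Saccades shorter than ``min_saccade_ms``
    are discarded; fixations are the inter-saccade intervals subject to the
    usual duration and missing-samples rules.
    """
    params = params or AdaptiveParams()
    vel = compute_velocity(rec)
    v, t = vel.v, vel.t
    defined = np.isfinite(v)
    if (rec.t[-1] - rec.t[0]) < params.noise_window_ms or defined.sum() < 2:
        raise InputError("recording too short for noise calibration")
    pt, _ = adaptive_peak_threshold(v, params.initial_peak_threshold_dps,
                                    params.lam, params.convergence_tol_dps,
                                    params.max_iterations)
    sub = v[defined & (v <= pt)]
    glob = (float(np.mean(sub)) if sub.size else 0.0,
            float(np.std(sub, ddof=1)) if sub.size > 1 else 0.0)

    peak_runs = _runs_true(np.nan_to_num(v, nan=-np.inf) > pt)
    sac_runs: list[tuple[int, int]] = []
    for a, b in peak_runs:
        mu1, sd1 = _local_stats(v, t, t[a] - params.noise_window_ms, t[a], glob)
        onset_thr = mu1 + params.onset_lambda * sd1
        i = a
        while i - 1 >= 0 and np.isfinite(v[i - 1]) and v[i - 1] > onset_thr:
            i -= 1
        mu2, sd2 = _local_stats(v, t, t[b], t[b] + params.noise_window_ms, glob)
        offset_thr = (params.offset_weight_alpha * onset_thr
                      + (1.0 - params.offset_weight_alpha)
                      * (mu2 + params.onset_lambda * sd2))
        j = b
        while j + 1 < rec.n and np.isfinite(v[j + 1]) and v[j + 1] > offset_thr:
            j += 1
        if sac_runs and i <= sac_runs[-1][1]:
            sac_runs[-1] = (sac_runs[-1][0], max(sac_runs[-1][1], j))
        else:
            sac_runs.append((i, j))
    return _build_events(rec, sac_runs, "adaptive", params, v,
                         params.min_fixation_ms,
                         params.missing_samples_threshold,
                         params.min_saccade_ms)


# ---------------------------------------------------------------------------
# I2MC

def _two_means_assignments(pts: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic Lloyd two-means on ordered (x, y) points.

    Seeds are the means of the first and second halves of the window, so a
    window containing a fixation-to-fixation transition starts well
    separated and converges identically on every run.
    """
    m = len(pts)
    half = m // 2
    c = np.vstack([pts[:half].mean(axis=0), pts[half:].mean(axis=0)])
    assign = np.zeros(m, dtype=int)
    for it in range(max_iter):
        d0 = np.sum((pts - c[0]) ** 2, axis=1)
        d1 = np.sum((pts - c[1]) ** 2, axis=1)
        new = (d1 < d0).astype(int)
        if it > 0 and np.array_equal(new, assign):
            break
        assign = new
        for k in (0, 1):
            sel = assign == k
            if sel.any():
                c[k] = pts[sel].mean(axis=0)
    return assign


def i2mc_transition_weights(rec: GazeRecording,
                            params: I2MCParams | None = None) -> np.ndarray:
    """Per-native-sample transition weights from sliding two-means windows.

    For every window position (stride ``step_ms``) and rate variant (native
    plus each block-downsampled copy), windows with enough valid data are
    split into two clusters; each sample where the cluster assignment
    switches receives weight 1/(switches in the window), every other covered
    sample receives 0.  The final weight is the mean over all (window,
    variant) contributions covering the sample; samples in a transition stand
    out because nearly every window sees the switch at them.
    """
    params = params or I2MCParams()
    if rec.unit != "deg":
        raise InputError("classify_i2mc requires a recording in degrees")
    n = rec.n
    native = rec.rate_hz or 1000.0 / rec.median_dt_ms()
    variants: list[tuple[GazeRecording, int]] = [(rec, 1)]
    for f in params.downsample_factors:
        ds = downsample_by_factor(rec, int(f))
        if np.sum((ds.t >= rec.t[0]) & (ds.t < rec.t[0] + params.window_ms)) >= 4:
            variants.append((ds, int(f)))
    w_sum = np.zeros(n)
    w_cnt = np.zeros(n)
    t0, t_last = rec.t[0], rec.t[-1]
    starts = np.arange(t0, max(t_last - params.window_ms, t0) + 1e-9,
                       params.step_ms)
    any_window = False
    for var, k in variants:
        vt, vx, vy, vvalid = var.t, var.x, var.y, var.valid
        for s in starts:
            sel = np.nonzero((vt >= s) & (vt < s + params.window_ms))[0]
            if sel.size < 2:
                continue
            ok = vvalid[sel]
            if ok.mean() < params.min_valid_prop_window or ok.sum() < 4:
                continue
            any_window = True
            vidx = sel[ok]
            pts = np.column_stack([vx[vidx], vy[vidx]])
            assign = _two_means_assignments(pts)
            switches = np.nonzero(np.diff(assign) != 0)[0] + 1  # later sample
            nsw = switches.size
            # native index range covered by this window in this variant
            lo = sel[0] * k
            hi = min((sel[-1] + 1) * k, n)
            w_cnt[lo:hi] += 1.0
            if nsw:
                # a switch at a downsampled sample maps to the first native
                # sample of its block (where the upsampled assignment changes)
                for sw in switches:
                    w_sum[min(vidx[sw] * k, n - 1)] += 1.0 / nsw
    if not any_window:
        raise InputError("insufficient data: no window held enough valid samples")
    with np.errstate(invalid="ignore"):
        return np.where(w_cnt > 0, w_sum / np.maximum(w_cnt, 1), 0.0)


def _refine_fixation_edges(rec: GazeRecording, a: int, b: int,
                           k: float) -> tuple[int, int] | None:
    """Shrink a candidate fixation to samples near its median position.

    A cluster switch localizes a transition at a single sample, so the slow
    head and tail of the saccade would otherwise be absorbed into the
    flanking fixations.  Walking inward from each edge, samples farther than
    ``k`` robust standard deviations (1.4826·MAD of the distance from the
    candidate's median position, with a small floor) are peeled off.
    Returns None when nothing survives.
    """
    sl = slice(a, b + 1)
    valid = rec.valid[sl]
    if valid.sum() < 2:
        return a, b
    xs, ys = rec.x[sl][valid], rec.y[sl][valid]
    mx, my = float(np.median(xs)), float(np.median(ys))
    d_all = np.hypot(rec.x[sl] - mx, rec.y[sl] - my)
    d_valid = np.hypot(xs - mx, ys - my)
    spread = 1.4826 * float(np.median(np.abs(d_valid - np.median(d_valid))))
    cut = k * max(spread, 0.02)  # floor: ~noise-free data still needs a band
    idx = np.arange(a, b + 1)
    inside = ~rec.valid[sl] | (d_all <= cut)  # invalid samples don't block
    lo, hi = 0, b - a
    while lo <= hi and not (rec.valid[sl][lo] and inside[lo]):
        lo += 1
    while hi >= lo and not (rec.valid[sl][hi] and inside[hi]):
        hi -= 1
    if hi < lo:
        return None
    return int(idx[lo]), int(idx[hi])


def classify_i2mc(rec: GazeRecording, params: I2MCParams | None = None) -> EventSet:
    """Two-means-clustering classification (robust to noise and data loss).

    Transition samples are those whose weight exceeds
    ``mean + weight_cutoff_sd·sd`` of the weight distribution; fixations are
    the maximal intervals between transitions, their edges refined to exclude
    saccade samples adjacent to the switch (``edge_refine_sd``), filtered by
    duration and the missing-samples rule, then merged within
    ``merge_dist_deg`` / ``merge_gap_ms``.
    """
    params = params or I2MCParams()
    w = i2mc_transition_weights(rec, params)
    cutoff = float(np.mean(w) + params.weight_cutoff_sd * np.std(w))
    transition = w > cutoff
    runs = _runs_true(transition)
    if params.edge_refine_sd is not None:
        new_trans = transition.copy()
        for a, b in _complement_segments(rec.n, runs):
            refined = _refine_fixation_edges(rec, a, b, params.edge_refine_sd)
            if refined is None:
                new_trans[a:b + 1] = True
                continue
            ra, rb = refined
            new_trans[a:ra] = True
            new_trans[rb + 1:b + 1] = True
        runs = _runs_true(new_trans)

    # candidate fixations between transitions; merge BEFORE the duration
    # filter so that fragments split by isolated weight spikes reassemble,
    # then apply the duration and missing-samples rules
    candidates = [event_from_samples(rec, a, b, FIXATION, "i2mc",
                                     edge_truncated=(a == 0 or b == rec.n - 1))
                  for a, b in _complement_segments(rec.n, runs)]
    es = EventSet(events=candidates, algorithm="i2mc",
                  params=_params_dict(params), recording=rec)
    if params.merge_dist_deg is not None and params.merge_gap_ms is not None:
        from .postprocess import merge_adjacent_fixations
        es = merge_adjacent_fixations(es, params.merge_dist_deg,
                                      params.merge_gap_ms)
    kept = []
    for f in es.fixations():
        if f.duration_ms < params.min_fixation_ms:
            continue
        sl = slice(f.first_sample, f.last_sample + 1)
        if (f.first_sample >= 0
                and np.mean(~rec.valid[sl]) > params.missing_samples_threshold):
            continue
        kept.append(f)
    # inter-fixation intervals become saccade events (no velocity metrics)
    spans = sorted((f.first_sample, f.last_sample) for f in kept
                   if f.first_sample >= 0)
    sacs = []
    for a, b in _complement_segments(rec.n, spans):
        try:
            sacs.append(event_from_samples(
                rec, a, b, SACCADE, "i2mc",
                edge_truncated=(a == 0 or b == rec.n - 1)))
        except ValueError:
            pass
    return EventSet(events=kept + sacs, algorithm="i2mc",
                    params=_params_dict(params), recording=rec)


CLASSIFIERS = {
    "ivt": (classify_ivt, IVTParams),
    "idt": (classify_idt, IDTParams),
    "adaptive": (classify_adaptive, AdaptiveParams),
    "i2mc": (classify_i2mc, I2MCParams),
}
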