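"""Gap interpolation, smoothing, and downsampling of raw gaze.

Blinks and tracking dropouts leave runs of invalid samples.  Short gaps
(default ≤ 75 ms) are bridged by linear interpolation anchored on a short
stretch of valid data on each side of the gap, so a single noisy sample next
to a blink does not skew the bridge.  Coordinates are then smoothed with a
centered moving median (or moving average) whose window never bridges invalid
runs.  Downsampling is block-averaging, which both lowers the rate and
suppresses noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GazeRecording, InputError

__all__ = ["PreprocessParams", "interpolate_gaps", "smooth_gaze",
           "downsample_gaze", "preprocess_gaze"]


@dataclass
class PreprocessParams:
    """Pre-processing settings.

    max_gap_ms : longest invalid run that will be interpolated (ms).
    margin_ms : span of valid data averaged on each side of a gap to anchor
        the interpolation (ms).
    smooth_window_ms : length of the smoothing window (ms).
    smooth_method : "median" or "average".
    """

    max_gap_ms: float = 75.0
    margin_ms: float = 10.0
    smooth_window_ms: float = 15.0
    smooth_method: str = "median"

    def __post_init__(self) -> None:
        if self.max_gap_ms < 0 or self.margin_ms < 0 or self.smooth_window_ms < 0:
            raise ValueError("durations must be >= 0")
        if self.smooth_method not in ("median", "average"):
            raise ValueError(f"unknown smooth_method {self.smooth_method!r}")


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of invalid samples as (first, last) inclusive indices."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j + 1 < n and not valid[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def interpolate_gaps(rec: GazeRecording,
                     params: PreprocessParams | None = None) -> GazeRecording:
    """Linearly interpolate short invalid runs; mark them as interpolated.

    A run is eligible if its duration (span of invalid samples plus one median
    inter-sample interval) is at most ``max_gap_ms`` and it has at least one
    valid sample on each side.  Each anchor is the mean coordinate of the
    valid samples within ``margin_ms`` adjacent to the gap (the nearest valid
    sample if the margin holds none); the interior is linear in time between
    the flanking valid samples.  Valid original samples are never modified.
    """
    params = params or PreprocessParams()
    out = rec.copy()
    if rec.n < 3 or rec.valid.all():
        return out
    dt = rec.median_dt_ms()
    t, x, y, valid = rec.t, rec.x, rec.y, rec.valid
    for i0, i1 in _invalid_runs(valid):
        if i0 == 0 or i1 == rec.n - 1:
            continue  # boundary gap: no anchor on one side
        gap_ms = (t[i1] - t[i0]) + dt
        if gap_ms > params.max_gap_ms:
            continue
        ib, ia = i0 - 1, i1 + 1  # flanking valid samples
        pre = np.nonzero(valid[:i0] & (t[:i0] >= t[ib] - params.margin_ms))[0]
        post_rel = np.nonzero(valid[ia:] & (t[ia:] <= t[ia] + params.margin_ms))[0]
        post = post_rel + ia
        bx = x[pre].mean() if pre.size else x[ib]
        by = y[pre].mean() if pre.size else y[ib]
        ax = x[post].mean() if post.size else x[ia]
        ay = y[post].mean() if post.size else y[ia]
        frac = (t[i0:i1 + 1] - t[ib]) / (t[ia] - t[ib])
        out.x[i0:i1 + 1] = bx + frac * (ax - bx)
        out.y[i0:i1 + 1] = by + frac * (ay - by)
        out.valid[i0:i1 + 1] = True
        out.interpolated[i0:i1 + 1] = True
    return out


def _window_samples(window_ms: float, rate_hz: float) -> int:
    w = int(round(window_ms * rate_hz / 1000.0))
    if w % 2 == 0:
        w = max(w - 1, 1)
    return max(w, 1)


def smooth_gaze(rec: GazeRecording,
                params: PreprocessParams | None = None) -> GazeRecording:
    """Smooth x and y with a centered moving median or average.

    The window spans ``round(smooth_window_ms · rate / 1000)`` samples (forced
    odd, minimum 1) but never bridges invalid samples: only the contiguous
    valid run containing the center sample contributes.  Invalid samples stay
    invalid and timestamps are untouched.
    """
    params = params or PreprocessParams()
    out = rec.copy()
    rate = rec.rate_hz or (1000.0 / rec.median_dt_ms() if rec.n >= 2 else 1.0)
    w = _window_samples(params.smooth_window_ms, rate)
    if w <= 1:
        return out
    half = w // 2
    reducer = np.median if params.smooth_method == "median" else np.mean
    valid = rec.valid
    n = rec.n
    # bounds of the contiguous valid run containing each sample
    run_start = np.empty(n, dtype=int)
    run_end = np.empty(n, dtype=int)
    s = 0
    for i in range(n):
        if not valid[i]:
            s = i + 1
            continue
        if i == 0 or not valid[i - 1]:
            s = i
        run_start[i] = s
    e = n - 1
    for i in range(n - 1, -1, -1):
        if not valid[i]:
            e = i - 1
            continue
        if i == n - 1 or not valid[i + 1]:
            e = i
        run_end[i] = e
    for i in range(n):
        if not valid[i]:
            continue
        lo = max(i - half, run_start[i])
        hi = min(i + half, run_end[i])
        out.x[i] = reducer(rec.x[lo:hi + 1])
        out.y[i] = reducer(rec.y[lo:hi + 1])
    return out


def downsample_gaze(rec: GazeRecording, target_hz: float) -> GazeRecording:
    """Downsample by block-averaging to approximately ``target_hz``.

    The native/target rate ratio is rounded to the nearest integer factor
    k ≥ 1; consecutive blocks of k samples collapse to one sample whose
    coordinate is the mean of the block's valid samples, whose timestamp is
    the block's first timestamp, and which is valid iff the block held at
    least one valid sample.
    """
    if rec.n < 2:
        raise InputError("cannot downsample a recording with < 2 samples")
    native = rec.rate_hz or 1000.0 / rec.median_dt_ms()
    if target_hz > native * 1.0000001:
        raise InputError(
            f"target rate {target_hz} Hz exceeds native rate {native:.1f} Hz")
    k = max(int(round(native / target_hz)), 1)
    return downsample_by_factor(rec, k)


def downsample_by_factor(rec: GazeRecording, k: int) -> GazeRecording:
    """Block-average every k consecutive samples into one (k ≥ 1)."""
    if k <= 1:
        return rec.copy()
    n_out = int(np.ceil(rec.n / k))
    t = np.empty(n_out)
    x = np.full(n_out, np.nan)
    y = np.full(n_out, np.nan)
    valid = np.zeros(n_out, dtype=bool)
    interp = np.zeros(n_out, dtype=bool)
    for b in range(n_out):
        sl = slice(b * k, min((b + 1) * k, rec.n))
        t[b] = rec.t[sl.start]
        ok = rec.valid[sl]
        if ok.any():
            valid[b] = True
            x[b] = rec.x[sl][ok].mean()
            y[b] = rec.y[sl][ok].mean()
            interp[b] = rec.interpolated[sl][ok].all()
    native = rec.rate_hz or 1000.0 / rec.median_dt_ms()
    return GazeRecording(t=t, x=x, y=y, valid=valid, unit=rec.unit,
                         geometry=rec.geometry, rate_hz=native / k,
                         interpolated=interp)


def preprocess_gaze(rec: GazeRecording,
                    params: PreprocessParams | None = None) -> GazeRecording:
    """Interpolate short gaps, then smooth — the standard cleaning pipeline."""
    params = params or PreprocessParams()
    return smooth_gaze(interpolate_gaps(rec, params), params)
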