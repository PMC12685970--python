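"""Per-sample angular velocity of the gaze trace.

Velocity is the Euclidean distance between consecutive samples divided by the
inter-sample interval, expressed in degrees per second.  It is assigned to the
*later* sample of each pair, so a saccade-onset sample is the first sample
whose velocity exceeds threshold.  Velocity is undefined (NaN) at the first
sample and wherever either bounding sample is invalid; classifiers treat
undefined velocity as "not above threshold" but never let it belong to a
saccade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GazeRecording, UnitError

__all__ = ["VelocityTrace", "compute_velocity"]


@dataclass
class VelocityTrace:
    """Angular speed aligned sample-for-sample with a recording.

    t : timestamps in ms (same grid as the source recording).
    v : speed in deg/s; NaN where undefined.
    """

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have the same length")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.v)


def compute_velocity(rec: GazeRecording,
                     smooth_window_ms: float = 0.0) -> VelocityTrace:
    """Sample-to-sample angular speed in deg/s.

    v[i] = ‖(x, y)[i] − (x, y)[i−1]‖ / (t[i] − t[i−1]) · 1000 when both
    samples are valid; NaN otherwise and at i = 0.  If ``smooth_window_ms`` is
    positive, the speed is additionally smoothed with a centered moving
    average whose window contributes only defined entries and never bridges
    undefined ones.
    """
    if rec.unit != "deg":
        raise UnitError(
            f"velocity requires a recording in degrees, got {rec.unit!r}; "
            "convert with gazekit.io.pixels_to_degrees first")
    n = rec.n
    v = np.full(n, np.nan)
    if n >= 2:
        dt = np.diff(rec.t)
        dx = np.diff(rec.x)
        dy = np.diff(rec.y)
        both = rec.valid[1:] & rec.valid[:-1]
        with np.errstate(invalid="ignore"):
            speed = np.hypot(dx, dy) / dt * 1000.0
        v[1:] = np.where(both, speed, np.nan)
    if smooth_window_ms > 0 and n >= 2:
        rate = rec.rate_hz or 1000.0 / rec.median_dt_ms()
        w = int(round(smooth_window_ms * rate / 1000.0))
        if w % 2 == 0:
            w = max(w - 1, 1)
        if w > 1:
            half = w // 2
            sm = v.copy()
            defined = np.isfinite(v)
            for i in range(n):
                if not defined[i]:
                    continue
                lo, hi = i, i
                while lo > max(0, i - half) and defined[lo - 1]:
                    lo -= 1
                while hi < min(n - 1, i + half) and defined[hi + 1]:
                    hi += 1
                sm[i] = np.mean(v[lo:hi + 1])
            v = sm
    return VelocityTrace(t=rec.t.copy(), v=v)
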