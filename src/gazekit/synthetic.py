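"""Synthetic scanpath generation with per-sample ground truth.

The simulator emits alternating fixations and saccades on a regular sampling
grid: each planned fixation is a stable position plus isotropic Gaussian
noise calibrated so the sample-to-sample RMSD equals ``noise_rms_deg`` (per
axis σ = rms/2: the difference of two i.i.d. per-axis draws has sd σ√2, and
two axes contribute quadratically).  Saccades follow a raised-cosine
displacement profile — unimodal velocity, zero at both endpoints — whose
duration defaults to a main-sequence-style rule ``21 + 2.2·amplitude``
(ms per degree).  Blinks/data loss are injected as declared invalid runs plus
independent per-sample loss.

This is the test substrate for every downstream stage: the emitted
:class:`GroundTruth` carries both per-sample labels and the true event table
in the same onset/offset convention the classifiers use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import Event, EventSet, FIXATION, SACCADE
from .io import GazeRecording

__all__ = ["SimSpec", "GroundTruth", "simulate_gaze", "fixture_spec"]

LABEL_LOST = -1


class SpecError(ValueError):
    """The simulation spec is internally inconsistent."""


def main_sequence_duration_ms(amplitude_deg: float) -> float:
    """Default saccade duration from amplitude: 21 + 2.2·amplitude (ms)."""
    return 21.0 + 2.2 * float(amplitude_deg)


@dataclass
class SimSpec:
    """Declarative description of a synthetic scanpath.

    fixations : sequence of (x_deg, y_deg, duration_ms).
    saccade_durations_ms : optional per-transition durations; derived from
        the amplitude via the main-sequence rule when None.
    noise_rms_deg : target sample-to-sample RMSD of the within-fixation noise.
    loss_runs : (start_ms, duration_ms) invalid runs (must not overlap).
    loss_prob : independent per-sample loss probability in [0, 1).
    """

    rate_hz: float = 1000.0
    fixations: Sequence[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.0, 0.0, 250.0), (5.0, 0.0, 250.0)])
    saccade_durations_ms: Sequence[float] | None = None
    noise_rms_deg: float = 0.0
    loss_runs: Sequence[tuple[float, float]] = field(default_factory=list)
    loss_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise SpecError("rate_hz must be > 0")
        if len(self.fixations) < 1:
            raise SpecError("need at least one planned fixation")
        if any(d <= 0 for _, _, d in self.fixations):
            raise SpecError("fixation durations must be positive")
        if self.noise_rms_deg < 0:
            raise SpecError("noise_rms_deg must be >= 0")
        if not 0.0 <= self.loss_prob < 1.0:
            raise SpecError("loss_prob must lie in [0, 1)")
        runs = sorted((float(s), float(d)) for s, d in self.loss_runs)
        for (s1, d1), (s2, _) in zip(runs, runs[1:]):
            if s1 + d1 > s2:
                raise SpecError("overlapping loss runs")
        if self.saccade_durations_ms is not None and len(
                self.saccade_durations_ms) != len(self.fixations) - 1:
            raise SpecError("need one saccade duration per transition")


@dataclass
class GroundTruth:
    """True event structure underlying a simulated recording.

    label : per-sample event kind ("fixation" | "saccade" | "lost").
    index : per-sample event index (which fixation/saccade), −1 where lost.
    events : the true EventSet (positions are the planned ones, noise-free).
    """

    label: np.ndarray
    index: np.ndarray
    events: EventSet


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    return (1.0 - np.cos(np.pi * u)) / 2.0


def simulate_gaze(spec: SimSpec) -> tuple[GazeRecording, GroundTruth]:
    """Render a spec into a recording plus ground truth.

    Deterministic given ``spec.seed``.  Sample count equals total planned
    duration times the rate; lost samples have NaN coordinates and
    ``valid=False`` but keep their underlying plan label in the truth's
    ``index`` for event bookkeeping (their ``label`` reads "lost").
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1000.0 / spec.rate_hz
    fx = [(float(x), float(y), float(d)) for x, y, d in spec.fixations]

    # timeline of (kind, event index, x0, y0, x1, y1, duration)
    segments = []
    for i, (x, y, d) in enumerate(fx):
        segments.append((FIXATION, i, x, y, x, y, d))
        if i + 1 < len(fx):
            x2, y2, _ = fx[i + 1]
            amp = float(np.hypot(x2 - x, y2 - y))
            if spec.saccade_durations_ms is not None:
                sd = float(spec.saccade_durations_ms[i])
            else:
                sd = main_sequence_duration_ms(amp)
            sd = max(np.ceil(sd / dt), 2) * dt  # cap to the sampling grid
            segments.append((SACCADE, i, x, y, x2, y2, sd))

    total_ms = sum(s[-1] for s in segments)
    n = int(round(total_ms / dt))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    kind = np.empty(n, dtype=object)
    index = np.full(n, -1, dtype=int)

    bounds = np.cumsum([0.0] + [s[-1] for s in segments])
    events: list[Event] = []
    for (seg, (kname, ei, x0, y0, x1, y1, d)), (b0, b1) in zip(
            enumerate(segments), zip(bounds[:-1], bounds[1:])):
        sel = (t >= b0 - 1e-9) & (t < b1 - 1e-9)
        if kname == FIXATION:
            x[sel], y[sel] = x0, y0
        else:
            u = (t[sel] - b0) / d
            prof = _raised_cosine(u)
            x[sel] = x0 + (x1 - x0) * prof
            y[sel] = y0 + (y1 - y0) * prof
        kind[sel] = kname
        index[sel] = ei
        ev = Event(kind=kname, onset_ms=float(b0), offset_ms=float(b1),
                   algorithm="truth")
        if kname == FIXATION:
            ev.x, ev.y = x0, y0
        else:
            ev.amplitude_deg = float(np.hypot(x1 - x0, y1 - y0))
            ev.peak_velocity_dps = ev.amplitude_deg * np.pi / (2.0 * d) * 1000.0
        events.append(ev)

    if spec.noise_rms_deg > 0:
        sigma = spec.noise_rms_deg / 2.0
        x += rng.normal(0.0, sigma, n)
        y += rng.normal(0.0, sigma, n)

    valid = np.ones(n, dtype=bool)
    for s, d in spec.loss_runs:
        valid[(t >= s) & (t < s + d)] = False
    if spec.loss_prob > 0:
        valid &= rng.random(n) >= spec.loss_prob
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)

    label = np.where(valid, kind, "lost")
    rec = GazeRecording(t=t, x=x, y=y, valid=valid, unit="deg",
                        rate_hz=spec.rate_hz)
    truth = GroundTruth(label=label, index=index,
                        events=EventSet(events=events, algorithm="truth",
                                        params={"seed": spec.seed},
                                        recording=rec))
    return rec, truth


def fixture_spec(name: str, seed: int = 0) -> SimSpec:
    """Packaged scanpath specs for examples and tests.

    ``clean-1200Hz`` mirrors a high-quality adult recording (low RMSD, no
    loss); ``noisy-lossy`` mirrors a low-quality recording with heavy data
    loss and coarse precision, the regime where simple classifiers break
    down.
    """
    plans = {
        "clean-1200Hz": SimSpec(
            rate_hz=1200.0,
            fixations=[(0.0, 0.0, 250.0), (4.0, 1.0, 200.0), (8.0, -1.0, 300.0),
                       (3.0, -3.0, 180.0), (-2.0, 0.5, 260.0), (1.5, 2.5, 220.0)],
            noise_rms_deg=0.12, loss_prob=0.0, seed=seed),
        "noisy-lossy": SimSpec(
            rate_hz=1200.0,
            fixations=[(0.0, 0.0, 300.0), (6.0, 0.0, 280.0), (-3.0, 2.0, 320.0),
                       (2.0, -2.0, 260.0), (7.0, 3.0, 300.0)],
            noise_rms_deg=0.36, loss_prob=0.6, seed=seed),
    }
    if name not in plans:
        raise KeyError(f"unknown fixture spec {name!r}; "
                       f"available: {sorted(plans)}")
    return plans[name]


def random_scanpath_spec(rng: np.random.Generator, *,
                         n_fixations: int = 10,
                         rate_hz: float = 1000.0,
                         duration_range_ms: tuple[float, float] = (150.0, 300.0),
                         amplitude_range_deg: tuple[float, float] = (2.0, 10.0),
                         noise_rms_deg: float = 0.0,
                         loss_prob: float = 0.0) -> SimSpec:
    """Draw a random fixation plan with main-sequence saccades.

    Fixation positions perform a random walk with step lengths in
    ``amplitude_range_deg`` and uniform directions; durations are uniform in
    ``duration_range_ms``.  The derived seed keeps the simulation
    reproducible from the caller's generator state.
    """
    pos = np.array([0.0, 0.0])
    fixations = []
    for _ in range(n_fixations):
        fixations.append((pos[0], pos[1],
                          rng.uniform(*duration_range_ms)))
        amp = rng.uniform(*amplitude_range_deg)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        pos = pos + amp * np.array([np.cos(ang), np.sin(ang)])
    return SimSpec(rate_hz=rate_hz, fixations=fixations,
                   noise_rms_deg=noise_rms_deg, loss_prob=loss_prob,
                   seed=int(rng.integers(0, 2 ** 31 - 1)))
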