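"""Classified gaze events (fixations and saccades) and event collections."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["Event", "EventSet", "event_from_samples"]

FIXATION = "fixation"
SACCADE = "saccade"


@dataclass
class Event:
    """One classified oculomotor event.

    Onset/offset are in ms on the recording's (re-based) clock; the offset is
    the timestamp of the first sample *after* the event (or the last sample
    plus one median interval at the recording edge), so durations are positive
    and abutting events tile the timeline.

    Fixations carry a centroid ``(x, y)`` in degrees (mean of valid
    constituent samples); saccades carry ``amplitude_deg`` and
    ``peak_velocity_dps`` where a velocity trace was available.
    ``prop_missing`` counts samples missing in the *original* recording, i.e.
    interpolated samples still count as missing.
    """

    kind: str
    onset_ms: float
    offset_ms: float
    x: float = float("nan")
    y: float = float("nan")
    amplitude_deg: float = float("nan")
    peak_velocity_dps: float = float("nan")
    rmsd_deg: float = float("nan")
    prop_missing: float = float("nan")
    algorithm: str = ""
    first_sample: int = -1
    last_sample: int = -1
    edge_truncated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (FIXATION, SACCADE):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.offset_ms > self.onset_ms:
            raise ValueError(
                f"event offset ({self.offset_ms}) must exceed onset ({self.onset_ms})")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def n_samples(self) -> int:
        if self.first_sample < 0:
            return 0
        return self.last_sample - self.first_sample + 1


@dataclass
class EventSet:
    """An ordered collection of events from one classification run.

    Invariants: events sorted by onset; same-kind events never overlap.  The
    producing algorithm and its parameter record travel with the set, and the
    source recording may be attached so post-processing can recompute
    per-event sample statistics.
    """

    events: list[Event] = field(default_factory=list)
    algorithm: str = ""
    params: dict = field(default_factory=dict)
    recording: object = None  # GazeRecording | None; kept loose to avoid cycles

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset_ms, e.kind))
        for kind in (FIXATION, SACCADE):
            prev = None
            for ev in self.events:
                if ev.kind != kind:
                    continue
                if prev is not None and ev.onset_ms < prev.offset_ms:
                    raise ValueError(
                        f"overlapping {kind}s at {prev.offset_ms} / {ev.onset_ms} ms")
                prev = ev

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def fixations(self) -> list[Event]:
        return [e for e in self.events if e.kind == FIXATION]

    def saccades(self) -> list[Event]:
        return [e for e in self.events if e.kind == SACCADE]

    def to_frame(self) -> pd.DataFrame:
        cols = ["kind", "onset_ms", "offset_ms", "duration_ms", "x", "y",
                "amplitude_deg", "peak_velocity_dps", "rmsd_deg",
                "prop_missing", "algorithm"]
        rows = [{c: getattr(e, c, None) if c != "duration_ms" else e.duration_ms
                 for c in cols} for e in self.events]
        return pd.DataFrame(rows, columns=cols)

    def replace_events(self, events: Iterable[Event]) -> "EventSet":
        return EventSet(events=list(events), algorithm=self.algorithm,
                        params=dict(self.params), recording=self.recording)


def _rmsd_of_samples(x: np.ndarray, y: np.ndarray, valid: np.ndarray) -> float:
    """Sample-to-sample RMS displacement over consecutive valid pairs."""
    ok = valid[:-1] & valid[1:]
    if not ok.any():
        return float("nan")
    dx = np.diff(x)[ok]
    dy = np.diff(y)[ok]
    return float(np.sqrt(np.mean(dx * dx + dy * dy)))


def event_from_samples(rec, i0: int, i1: int, kind: str, algorithm: str = "",
                       velocity: np.ndarray | None = None,
                       edge_truncated: bool = False) -> Event:
    """Build an Event from the recording samples ``i0..i1`` inclusive.

    Fills centroid (fixations), amplitude and peak velocity (saccades, when a
    velocity trace is supplied), within-event RMSD, and the proportion of
    originally-missing samples.
    """
    n = rec.n
    onset = float(rec.t[i0])
    offset = float(rec.t[i1 + 1]) if i1 + 1 < n else float(rec.t[i1] + rec.median_dt_ms())
    sl = slice(i0, i1 + 1)
    valid = rec.valid[sl]
    ev = Event(kind=kind, onset_ms=onset, offset_ms=offset, algorithm=algorithm,
               first_sample=i0, last_sample=i1, edge_truncated=edge_truncated)
    ev.prop_missing = float(np.mean(rec.missing[sl]))
    ev.rmsd_deg = _rmsd_of_samples(rec.x[sl], rec.y[sl], valid)
    if kind == FIXATION:
        if valid.any():
            ev.x = float(np.mean(rec.x[sl][valid]))
            ev.y = float(np.mean(rec.y[sl][valid]))
    else:
        idx = np.nonzero(valid)[0]
        if idx.size >= 2:
            a, b = idx[0] + i0, idx[-1] + i0
            ev.amplitude_deg = float(np.hypot(rec.x[b] - rec.x[a],
                                              rec.y[b] - rec.y[a]))
        if velocity is not None:
            v = velocity[sl]
            if np.isfinite(v).any():
                ev.peak_velocity_dps = float(np.nanmax(v))
    return ev
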