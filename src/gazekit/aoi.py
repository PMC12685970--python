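"""Area-of-interest definitions and gaze statistics.

AOIs are named rectangles or ellipses in the same unit as the data they are
applied to.  Statistics are computed either from classified fixations (a
fixation belongs to an AOI when its centroid is inside, by default) or from
raw samples (dwell proportion — the mode of choice when fixation
classification is unreliable, e.g. in infant data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import EventSet, FIXATION
from .io import GazeRecording, InputError, UnitError

__all__ = ["AOI", "point_in_aoi", "aoi_test", "load_aois", "save_aois"]

MEMBERSHIP_STRATEGIES = ("centroid", "any-sample", "majority-sample")


@dataclass(frozen=True)
class AOI:
    """A named screen region.

    shape : "rectangle" with coords (x_min, y_min, x_max, y_max) or
            "ellipse" with coords (center_x, center_y, radius_x, radius_y).
    unit : unit tag that must match the data the AOI is applied to.
    """

    name: str
    shape: str
    coords: tuple[float, float, float, float]
    unit: str = "deg"

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown AOI shape {self.shape!r}")
        c = tuple(float(v) for v in self.coords)
        object.__setattr__(self, "coords", c)
        if self.shape == "rectangle":
            if not (c[2] > c[0] and c[3] > c[1]):
                raise ValueError(f"rectangle {self.name!r} has non-positive extent")
        else:
            if not (c[2] > 0 and c[3] > 0):
                raise ValueError(f"ellipse {self.name!r} has non-positive radii")

    def contains(self, x, y):
        c = self.coords
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "rectangle":
            return (c[0] <= x) & (x <= c[2]) & (c[1] <= y) & (y <= c[3])
        return (((x - c[0]) / c[2]) ** 2 + ((y - c[1]) / c[3]) ** 2) <= 1.0


def point_in_aoi(p: tuple[float, float], aoi: AOI, unit: str | None = None) -> bool:
    """Whether the point lies inside the AOI (boundaries inclusive)."""
    if unit is not None and unit != aoi.unit:
        raise UnitError(f"point unit {unit!r} does not match AOI unit {aoi.unit!r}")
    return bool(aoi.contains(p[0], p[1]))


def _check_unique(aois: Sequence[AOI]) -> None:
    names = [a.name for a in aois]
    if len(set(names)) != len(names):
        raise ValueError("AOI names must be unique within a set")


def _fixation_in_aoi(ev, aoi: AOI, rec: GazeRecording | None,
                     strategy: str) -> bool:
    if strategy == "centroid" or rec is None or ev.first_sample < 0:
        return bool(aoi.contains(ev.x, ev.y))
    sl = slice(ev.first_sample, ev.last_sample + 1)
    ok = rec.valid[sl]
    if not ok.any():
        return False
    inside = aoi.contains(rec.x[sl][ok], rec.y[sl][ok])
    return bool(inside.any()) if strategy == "any-sample" else bool(
        inside.mean() > 0.5)


def aoi_test(data, aois: Iterable[AOI],
             segment: tuple[float, float] | None = None,
             strategy: str = "centroid") -> pd.DataFrame:
    """AOI statistics over a time segment.

    Fixation mode (``data`` is an EventSet): per AOI, the number of
    fixations, accumulated fixation time (clipped to the segment), and the
    latency from segment start to the first belonging fixation; a shared
    ``latency_first_outside_ms`` gives the first fixation falling in no AOI.
    Fixations that began before the segment contribute clipped time but not
    latency.  Sample mode (``data`` is a GazeRecording): per AOI, the
    proportion of valid in-segment samples inside (``dwell_proportion``),
    plus an ``outside`` row; with disjoint AOIs the proportions sum to 1.

    Overlapping AOIs are allowed — a fixation may count in several; the
    ``overlapped`` column flags rows affected.
    """
    aois = list(aois)
    _check_unique(aois)
    if strategy not in MEMBERSHIP_STRATEGIES:
        raise ValueError(f"unknown membership strategy {strategy!r}")

    if isinstance(data, EventSet):
        return _aoi_test_fixations(data, aois, segment, strategy)
    if isinstance(data, GazeRecording):
        return _aoi_test_samples(data, aois, segment)
    raise TypeError("data must be an EventSet or a GazeRecording")


def _segment_or_range(segment, t0, t1):
    if segment is None:
        return float(t0), float(t1)
    s0, s1 = float(segment[0]), float(segment[1])
    if not s1 > s0:
        raise InputError("segment must have positive length")
    return s0, s1


def _aoi_test_fixations(events: EventSet, aois, segment, strategy):
    fx = events.fixations()
    if fx:
        t0 = min(e.onset_ms for e in fx)
        t1 = max(e.offset_ms for e in fx)
    else:
        t0, t1 = 0.0, 1.0
    s0, s1 = _segment_or_range(segment, t0, t1)
    rec = events.recording
    rows = []
    membership = np.zeros((len(fx), len(aois)), dtype=bool)
    for i, ev in enumerate(fx):
        for j, aoi in enumerate(aois):
            membership[i, j] = _fixation_in_aoi(ev, aoi, rec, strategy)
    for j, aoi in enumerate(aois):
        n = 0
        total = 0.0
        latency = float("nan")
        for i, ev in enumerate(fx):
            clip = min(ev.offset_ms, s1) - max(ev.onset_ms, s0)
            if clip <= 0 or not membership[i, j]:
                continue
            n += 1
            total += clip
            if np.isnan(latency) and ev.onset_ms >= s0:
                latency = ev.onset_ms - s0
        rows.append({
            "aoi": aoi.name, "n_fixations": n,
            "total_fixation_time_ms": total,
            "latency_first_inside_ms": latency,
            "overlapped": bool((membership[:, j]
                                & membership[:, np.arange(len(aois)) != j].any(axis=1)
                                ).any()) if len(aois) > 1 else False,
        })
    # first fixation belonging to no AOI
    lat_out = float("nan")
    for i, ev in enumerate(fx):
        clip = min(ev.offset_ms, s1) - max(ev.onset_ms, s0)
        if clip <= 0 or membership[i].any() or ev.onset_ms < s0:
            continue
        lat_out = ev.onset_ms - s0
        break
    df = pd.DataFrame(rows)
    df["latency_first_outside_ms"] = lat_out
    return df


def _aoi_test_samples(rec: GazeRecording, aois, segment):
    s0, s1 = _segment_or_range(segment, rec.t[0], rec.t[-1] + rec.median_dt_ms()
                               if rec.n >= 2 else rec.t[0] + 1.0)
    sel = (rec.t >= s0) & (rec.t < s1) & rec.valid
    n_valid = int(sel.sum())
    rows = []
    inside_any = np.zeros(rec.n, dtype=bool)
    for aoi in aois:
        inside = np.zeros(rec.n, dtype=bool)
        inside[sel] = aoi.contains(rec.x[sel], rec.y[sel])
        inside_any |= inside
        rows.append({"aoi": aoi.name,
                     "n_samples": int(inside.sum()),
                     "dwell_proportion": (inside.sum() / n_valid
                                          if n_valid else float("nan"))})
    rows.append({"aoi": "outside",
                 "n_samples": int(n_valid - inside_any.sum()),
                 "dwell_proportion": ((n_valid - inside_any.sum()) / n_valid
                                      if n_valid else float("nan"))})
    return pd.DataFrame(rows)


def save_aois(aois: Iterable[AOI], path: str | Path) -> None:
    """Write AOIs as a JSON array of {name, shape, coords, unit}."""
    payload = [{"name": a.name, "shape": a.shape,
                "coords": list(a.coords), "unit": a.unit} for a in aois]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_aois(path: str | Path) -> list[AOI]:
    """Read AOIs from the JSON format written by :func:`save_aois`."""
    payload = json.loads(Path(path).read_text())
    aois = [AOI(name=d["name"], shape=d["shape"],
                coords=tuple(d["coords"]), unit=d.get("unit", "deg"))
            for d in payload]
    _check_unique(aois)
    return aois
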