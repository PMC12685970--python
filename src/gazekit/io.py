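"""Reading and writing tabular gaze data.

Screen-based eye trackers deliver a per-sample stream of timestamps and X/Y
gaze coordinates, usually as CSV/TSV (or xlsx) with vendor-specific column
names.  This module turns such tables into :class:`GazeRecording` objects,
converts pixel (or screen-proportion) coordinates to degrees of visual angle,
and writes classified events back out as CSV.

All downstream analysis uses canonical units: degrees for space and
milliseconds for time.  Timestamps are re-based so the first sample is at 0 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "GazeRecording",
    "read_gaze_table",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "proportion_to_pixels",
    "estimate_sampling_rate",
    "write_events_table",
    "read_events_table",
    "write_recording",
]

VALID_UNITS = ("px", "deg", "prop")


class ConfigurationError(ValueError):
    """A required column, unit or geometry is missing or inconsistent."""


class InputError(ValueError):
    """The data themselves violate a precondition (e.g. non-monotone time)."""


class UnitError(ValueError):
    """An operation received coordinates in the wrong unit."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Viewing geometry needed to convert pixels to degrees of visual angle.

    Parameters
    ----------
    distance_cm : float
        Viewing distance from eye to screen, cm.
    screen_width_cm, screen_height_cm : float
        Physical size of the display area, cm.
    res_x_px, res_y_px : int
        Display resolution in pixels.
    """

    distance_cm: float
    screen_width_cm: float
    screen_height_cm: float
    res_x_px: int
    res_y_px: int

    def __post_init__(self) -> None:
        for name in ("distance_cm", "screen_width_cm", "screen_height_cm",
                     "res_x_px", "res_y_px"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"ScreenGeometry.{name} must be > 0")


@dataclass
class GazeRecording:
    """A per-sample gaze time series with validity flags.

    Attributes
    ----------
    t : ndarray
        Timestamps in ms, strictly increasing, re-based to 0 at the first
        sample.
    x, y : ndarray
        Gaze coordinates in ``unit``.  Values at invalid samples are
        meaningless (typically NaN) and ignored everywhere.
    valid : ndarray of bool
        True where the sample holds a usable gaze coordinate.
    interpolated : ndarray of bool
        True where a sample was reconstructed by gap interpolation; such
        samples are valid for classification but still count as missing for
        data-loss metrics.
    unit : {"px", "deg", "prop"}
    geometry : ScreenGeometry, optional
    rate_hz : float, optional
        Nominal sampling rate; estimated from timestamps when absent.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    unit: str = "deg"
    geometry: ScreenGeometry | None = None
    rate_hz: float | None = None
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.t.shape, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid)
                == len(self.interpolated) == n):
            raise InputError("t, x, y, valid must all have the same length")
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if n >= 2:
            bad = np.nonzero(np.diff(self.t) <= 0)[0]
            if bad.size:
                raise InputError(
                    f"timestamps must be strictly increasing; first violation "
                    f"at index {int(bad[0]) + 1}")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n else 0.0

    @property
    def missing(self) -> np.ndarray:
        """Samples missing in the original recording (pre-interpolation)."""
        return ~self.valid | self.interpolated

    def median_dt_ms(self) -> float:
        if self.n < 2:
            raise InputError("need at least 2 samples")
        return float(np.median(np.diff(self.t)))

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            t=self.t.copy(), x=self.x.copy(), y=self.y.copy(),
            valid=self.valid.copy(), unit=self.unit, geometry=self.geometry,
            rate_hz=self.rate_hz, interpolated=self.interpolated.copy())


def read_gaze_table(
    path: str | Path,
    column_map: Mapping[str, str | Sequence[str]] | None = None,
    unit: str = "px",
    geometry: ScreenGeometry | None = None,
    *,
    delimiter: str | None = None,
    time_unit: str = "ms",
    rate_hz: float | None = None,
) -> GazeRecording:
    """Read a tabular gaze file (CSV/TSV/xlsx) into a :class:`GazeRecording`.

    Parameters
    ----------
    path : path
        CSV/TSV (delimiter sniffed from the extension unless given) or xlsx.
    column_map : mapping
        Keys ``t``, ``x``, ``y`` and optionally ``valid``.  ``x``/``y`` may
        each map to a pair of column names (left eye, right eye); the two
        eyes are then averaged over whichever is valid, and the sample is
        invalid only when both are.
    unit : {"px", "deg", "prop"}
        Unit of the coordinate columns.
    time_unit : {"ms", "s", "us"}
        Unit of the timestamp column; converted to ms.

    Rows with non-finite coordinates, or a falsy explicit validity column,
    become ``valid=False``.  Timestamps are re-based to 0.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"gaze file not found: {path}")
    column_map = dict(column_map or {"t": "t", "x": "x", "y": "y"})
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        if delimiter is None:
            delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=delimiter, comment="#")

    for key in ("t", "x", "y"):
        if key not in column_map:
            raise ConfigurationError(f"column_map must define {key!r}")
        cols = column_map[key]
        for col in ([cols] if isinstance(cols, str) else list(cols)):
            if col not in df.columns:
                raise ConfigurationError(
                    f"column {col!r} (mapped to {key!r}) not found in {path.name}")

    t = pd.to_numeric(df[column_map["t"]], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("non-numeric timestamps")
    scale = {"ms": 1.0, "s": 1000.0, "us": 1e-3}.get(time_unit)
    if scale is None:
        raise ConfigurationError(f"unknown time_unit {time_unit!r}")
    t = (t - t[0]) * scale

    def _coord(key: str) -> tuple[np.ndarray, np.ndarray]:
        cols = column_map[key]
        if isinstance(cols, str):
            v = pd.to_numeric(df[cols], errors="coerce").to_numpy(dtype=float)
            return v, np.isfinite(v)
        # binocular: average valid eyes, invalid iff both invalid
        vals = [pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
                for c in cols]
        stacked = np.vstack(vals)
        finite = np.isfinite(stacked)
        with np.errstate(invalid="ignore"):
            mean = np.where(finite.any(axis=0),
                            np.nansum(np.where(finite, stacked, 0.0), axis=0)
                            / np.maximum(finite.sum(axis=0), 1),
                            np.nan)
        return mean, finite.any(axis=0)

    x, xok = _coord("x")
    y, yok = _coord("y")
    valid = xok & yok
    if "valid" in column_map:
        col = column_map["valid"]
        if col not in df.columns:
            raise ConfigurationError(f"validity column {col!r} not found")
        flags = df[col]
        if flags.dtype == object:
            explicit = flags.astype(str).str.strip().str.lower().isin(
                ("1", "true", "t", "yes", "valid")).to_numpy()
        else:
            explicit = pd.to_numeric(flags, errors="coerce").fillna(0).to_numpy() > 0
        valid &= explicit
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeRecording(t=t, x=x, y=y, valid=valid, unit=unit,
                         geometry=geometry, rate_hz=rate_hz)


def _px_per_cm(geometry: ScreenGeometry) -> tuple[float, float]:
    return (geometry.res_x_px / geometry.screen_width_cm,
            geometry.res_y_px / geometry.screen_height_cm)


def pixels_to_degrees(rec: GazeRecording) -> GazeRecording:
    """Convert a pixel-unit recording to degrees of visual angle.

    Each axis is converted independently: the offset from the screen center in
    cm subtends ``atan(offset / distance)`` at the eye.  This is exact (not a
    small-angle approximation) and strictly monotone, hence invertible.
    """
    if rec.unit == "prop":
        rec = proportion_to_pixels(rec)
    if rec.unit != "px":
        raise UnitError(f"pixels_to_degrees expects px input, got {rec.unit!r}")
    if rec.geometry is None:
        raise ConfigurationError("pixels_to_degrees requires screen geometry")
    g = rec.geometry
    ppcm_x, ppcm_y = _px_per_cm(g)
    cx, cy = g.res_x_px / 2.0, g.res_y_px / 2.0
    x_deg = np.degrees(np.arctan((rec.x - cx) / ppcm_x / g.distance_cm))
    y_deg = np.degrees(np.arctan((rec.y - cy) / ppcm_y / g.distance_cm))
    out = rec.copy()
    out.x, out.y, out.unit = x_deg, y_deg, "deg"
    return out


def degrees_to_pixels(rec: GazeRecording) -> GazeRecording:
    """Inverse of :func:`pixels_to_degrees` (requires the same geometry)."""
    if rec.unit != "deg":
        raise UnitError(f"degrees_to_pixels expects deg input, got {rec.unit!r}")
    if rec.geometry is None:
        raise ConfigurationError("degrees_to_pixels requires screen geometry")
    g = rec.geometry
    ppcm_x, ppcm_y = _px_per_cm(g)
    cx, cy = g.res_x_px / 2.0, g.res_y_px / 2.0
    x_px = np.tan(np.radians(rec.x)) * g.distance_cm * ppcm_x + cx
    y_px = np.tan(np.radians(rec.y)) * g.distance_cm * ppcm_y + cy
    out = rec.copy()
    out.x, out.y, out.unit = x_px, y_px, "px"
    return out


def proportion_to_pixels(rec: GazeRecording) -> GazeRecording:
    """Convert screen-proportion coordinates ([0,1] per axis) to pixels."""
    if rec.unit != "prop":
        raise UnitError(f"proportion_to_pixels expects prop input, got {rec.unit!r}")
    if rec.geometry is None:
        raise ConfigurationError("proportion_to_pixels requires screen geometry")
    out = rec.copy()
    out.x = rec.x * rec.geometry.res_x_px
    out.y = rec.y * rec.geometry.res_y_px
    out.unit = "px"
    return out


def to_degrees(rec: GazeRecording) -> GazeRecording:
    """Coerce any supported unit to degrees (no-op if already deg)."""
    if rec.unit == "deg":
        return rec
    return pixels_to_degrees(rec)


def estimate_sampling_rate(rec: GazeRecording) -> float:
    """Estimate the sampling rate as 1000 / median inter-sample interval (Hz).

    The median makes the estimate robust to occasional dropped samples.
    """
    if rec.n < 2:
        raise InputError("need at least 2 samples to estimate a sampling rate")
    return 1000.0 / rec.median_dt_ms()


_EVENT_COLUMNS = ["kind", "onset_ms", "offset_ms", "duration_ms", "x", "y",
                  "amplitude_deg", "peak_velocity_dps", "rmsd_deg",
                  "prop_missing", "algorithm"]


def write_events_table(events, path: str | Path) -> None:
    """Write an EventSet as CSV, one row per event.

    The producing algorithm's parameters are serialized in ``#``-prefixed
    header comment lines so an events file documents how it was made.
    """
    path = Path(path)
    df = events.to_frame()
    for col in _EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[_EVENT_COLUMNS]
    try:
        with open(path, "w") as fh:
            fh.write(f"# algorithm: {events.algorithm}\n")
            for k, v in sorted((events.params or {}).items()):
                fh.write(f"# param {k} = {v}\n")
            df.to_csv(fh, index=False)
    except OSError as exc:
        raise IOError(f"cannot write events table to {path}: {exc}") from exc


def read_events_table(path: str | Path):
    """Read an events CSV written by :func:`write_events_table`."""
    from .events import Event, EventSet

    path = Path(path)
    algorithm, params = "", {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("algorithm:"):
                algorithm = body.split(":", 1)[1].strip()
            elif body.startswith("param "):
                k, _, v = body[6:].partition("=")
                params[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    evs = []
    for row in df.itertuples(index=False):
        evs.append(Event(
            kind=row.kind, onset_ms=float(row.onset_ms),
            offset_ms=float(row.offset_ms),
            x=float(row.x), y=float(row.y),
            amplitude_deg=float(row.amplitude_deg),
            peak_velocity_dps=float(row.peak_velocity_dps),
            rmsd_deg=float(row.rmsd_deg), prop_missing=float(row.prop_missing),
            algorithm=str(row.algorithm)))
    return EventSet(events=evs, algorithm=algorithm, params=params)


def write_recording(rec: GazeRecording, path: str | Path) -> None:
    """Write a recording as CSV with columns t,x,y,valid,interpolated,unit."""
    df = pd.DataFrame({
        "t": rec.t, "x": rec.x, "y": rec.y,
        "valid": rec.valid.astype(int),
        "interpolated": rec.interpolated.astype(int),
        "unit": rec.unit,
    })
    df.to_csv(path, index=False)


def read_recording(path: str | Path,
                   geometry: ScreenGeometry | None = None) -> GazeRecording:
    """Read a recording CSV written by :func:`write_recording`."""
    df = pd.read_csv(path)
    unit = str(df["unit"].iloc[0]) if "unit" in df.columns and len(df) else "deg"
    valid = df["valid"].to_numpy() > 0 if "valid" in df.columns else None
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    interp = (df["interpolated"].to_numpy() > 0
              if "interpolated" in df.columns else None)
    return GazeRecording(t=df["t"].to_numpy(dtype=float), x=x, y=y,
                         valid=valid, unit=unit, geometry=geometry,
                         interpolated=interp)
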