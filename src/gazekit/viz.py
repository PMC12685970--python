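"""Plotting for quality control and publication figures.

All functions render to a file with the Agg backend, return the output path,
and never mutate their inputs.  When a background stimulus image is given,
plots use screen orientation (origin top-left, y down); degree-unit plots
without a background use Cartesian orientation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .events import EventSet, FIXATION, SACCADE
from .io import GazeRecording, InputError
from .velocity import VelocityTrace

__all__ = ["plot_fixations_2d", "plot_timeseries", "plot_velocity",
           "plot_saccade_profiles", "plot_algorithm_quality", "scanpath_plot",
           "draw_aois"]

_COLORS = ["tab:blue", "tab:orange", "tab:green", "tab:red",
           "tab:purple", "tab:brown"]


def _finish(fig, out: str | Path) -> Path:
    out = Path(out)
    fig.savefig(out, dpi=100, metadata={"Software": None}
                if out.suffix.lower() == ".png" else None)
    plt.close(fig)
    return out


def _maybe_background(ax, background):
    if background is None:
        return
    from PIL import Image
    img = np.asarray(Image.open(background))
    ax.imshow(img, origin="upper")
    ax.set_xlabel("x (px, screen orientation)")
    ax.set_ylabel("y (px, y down)")


def plot_fixations_2d(rec: GazeRecording, sets: Sequence[EventSet] | EventSet,
                      out: str | Path, background=None) -> Path:
    """Raw samples overlaid with fixation centroids of up to six event sets.

    Marker area scales with fixation duration; the legend names each set's
    algorithm and key parameters.
    """
    if isinstance(sets, EventSet):
        sets = [sets]
    if len(sets) > 6:
        raise ValueError("at most 6 event sets can be overlaid")
    fig, ax = plt.subplots(figsize=(7, 6))
    _maybe_background(ax, background)
    ok = rec.valid
    ax.plot(rec.x[ok], rec.y[ok], ".", ms=1.5, color="0.6", label="samples")
    for es, color in zip(sets, _COLORS):
        fx = es.fixations()
        if fx:
            dur = np.array([f.duration_ms for f in fx])
            ax.scatter([f.x for f in fx], [f.y for f in fx],
                       s=10 + dur / 4.0, alpha=0.6, color=color,
                       label=_set_label(es))
        else:
            ax.scatter([], [], color=color, label=_set_label(es))
    if background is None:
        ax.set_xlabel(f"x ({rec.unit})")
        ax.set_ylabel(f"y ({rec.unit}, y up)")
    ax.legend(loc="best", fontsize=8)
    return _finish(fig, out)


def _set_label(es: EventSet) -> str:
    extras = {k: v for k, v in (es.params or {}).items()
              if k in ("velocity_threshold_dps", "dispersion_threshold_deg",
                       "window_ms", "initial_peak_threshold_dps")}
    suffix = ", ".join(f"{k}={v}" for k, v in extras.items())
    return es.algorithm + (f" ({suffix})" if suffix else "")


def plot_timeseries(rec_a: GazeRecording, rec_b: GazeRecording | None = None,
                    sets: Sequence[EventSet] | None = None, axis: str = "x",
                    span: tuple[float, float] | None = None,
                    out: str | Path = "timeseries.png") -> Path:
    """Coordinate-versus-time plot with optional second trace and fixations.

    Samples appear as lines broken at invalid runs; each event set adds a
    step-line holding the fixation centroid across its span — the layout used
    to compare raw versus preprocessed data or raw versus classified output.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if span is not None and not span[1] > span[0]:
        raise InputError("span must have positive length")
    fig, ax = plt.subplots(figsize=(9, 4))
    for rec, name, color in ((rec_a, "raw", "0.4"),
                             (rec_b, "processed", "tab:blue")):
        if rec is None:
            continue
        sel = np.ones(rec.n, dtype=bool)
        if span is not None:
            sel = (rec.t >= span[0]) & (rec.t < span[1])
        coord = np.where(rec.valid, getattr(rec, axis), np.nan)
        ax.plot(rec.t[sel], coord[sel], color=color, lw=0.8, label=name)
    for es, color in zip(sets or [], _COLORS[2:]):
        for f in es.fixations():
            if span is not None and (f.offset_ms < span[0] or f.onset_ms > span[1]):
                continue
            val = f.x if axis == "x" else f.y
            ax.hlines(val, f.onset_ms, f.offset_ms, color=color, lw=2)
        ax.plot([], [], color=color, lw=2, label=_set_label(es))
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"{axis} ({rec_a.unit})")
    ax.legend(loc="best", fontsize=8)
    return _finish(fig, out)


def plot_velocity(vel: VelocityTrace, threshold_dps: float | None = None,
                  span: tuple[float, float] | None = None,
                  out: str | Path = "velocity.png") -> Path:
    """Sample-to-sample speed against time, with an optional dashed
    threshold line marking a proposed saccade cutoff."""
    fig, ax = plt.subplots(figsize=(9, 4))
    sel = np.ones(len(vel.t), dtype=bool)
    if span is not None:
        if not span[1] > span[0]:
            raise InputError("span must have positive length")
        sel = (vel.t >= span[0]) & (vel.t < span[1])
    ax.plot(vel.t[sel], vel.v[sel], color="tab:blue", lw=0.8)
    if threshold_dps is not None:
        ax.axhline(threshold_dps, ls="--", color="k",
                   label=f"threshold {threshold_dps:g}°/s")
        ax.legend(fontsize=8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("velocity (deg/s)")
    return _finish(fig, out)


def plot_saccade_profiles(rec: GazeRecording, events: EventSet,
                          out: str | Path = "profiles.png") -> Path:
    """Overlaid velocity-versus-time-from-onset curves, one per saccade."""
    from .velocity import compute_velocity
    vel = compute_velocity(rec)
    fig, ax = plt.subplots(figsize=(6, 4))
    for sac in events.saccades():
        sel = (rec.t >= sac.onset_ms) & (rec.t < sac.offset_ms)
        ax.plot(rec.t[sel] - sac.onset_ms, vel.v[sel], lw=1.0, alpha=0.7)
    ax.set_xlabel("time from saccade onset (ms)")
    ax.set_ylabel("velocity (deg/s)")
    return _finish(fig, out)


def plot_algorithm_quality(summary, out: str | Path = "quality.png") -> Path:
    """Bar panels of the per-algorithm fixation summary table."""
    metrics = ["n_fixations", "mean_duration_ms", "mean_rmsd_deg",
               "mean_prop_missing"]
    fig, axes = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 3.5))
    for ax, metric in zip(np.atleast_1d(axes), metrics):
        ax.bar(summary["algorithm"], summary[metric],
               color=_COLORS[:len(summary)])
        ax.set_title(metric, fontsize=9)
        ax.tick_params(axis="x", rotation=45, labelsize=8)
    fig.tight_layout()
    return _finish(fig, out)


def scanpath_plot(sets, background=None,
                  span: tuple[float, float] | None = None,
                  out: str | Path = "scanpath.png", animate: bool = False,
                  ms_per_frame: float = 200.0) -> Path:
    """Numbered fixation sequences joined by lines, one color per group.

    ``sets`` is a mapping of group name → list of EventSets (or a single
    EventSet).  With ``animate=True`` a GIF is written whose frames advance
    in event time at ``ms_per_frame`` per frame.
    """
    if isinstance(sets, EventSet):
        sets = {"all": [sets]}
    if isinstance(sets, (list, tuple)):
        sets = {"all": list(sets)}

    def _draw(ax, t_max=None):
        _maybe_background(ax, background)
        for (group, group_sets), color in zip(sets.items(), _COLORS):
            for es in group_sets:
                fx = [f for f in es.fixations()
                      if (span is None or span[0] <= f.onset_ms < span[1])
                      and (t_max is None or f.onset_ms <= t_max)]
                if not fx:
                    continue
                xs = [f.x for f in fx]
                ys = [f.y for f in fx]
                ax.plot(xs, ys, "-o", color=color, alpha=0.6, ms=6)
                for i, f in enumerate(fx, start=1):
                    ax.annotate(str(i), (f.x, f.y), fontsize=7,
                                ha="center", va="center")
            ax.plot([], [], "-o", color=color, label=group)
        ax.legend(loc="best", fontsize=8)

    out = Path(out)
    if not animate:
        fig, ax = plt.subplots(figsize=(7, 6))
        _draw(ax)
        return _finish(fig, out)

    onsets = [f.onset_ms for g in sets.values() for es in g
              for f in es.fixations()]
    t0 = min(onsets) if onsets else 0.0
    t1 = max(onsets) if onsets else 0.0
    frame_times = np.arange(t0, t1 + ms_per_frame, ms_per_frame)
    from PIL import Image
    import io as _io
    frames = []
    for tm in frame_times:
        fig, ax = plt.subplots(figsize=(7, 6))
        _draw(ax, t_max=tm)
        buf = _io.BytesIO()
        fig.savefig(buf, format="png", dpi=80)
        plt.close(fig)
        buf.seek(0)
        frames.append(Image.open(buf).convert("P"))
    frames[0].save(out, save_all=True, append_images=frames[1:],
                   duration=int(ms_per_frame), loop=0)
    return out


def draw_aois(aois, out: str | Path, background=None,
              unit_label: str | None = None) -> Path:
    """Render AOI outlines (optionally over a stimulus image) for checking."""
    from matplotlib.patches import Rectangle, Ellipse
    fig, ax = plt.subplots(figsize=(7, 6))
    _maybe_background(ax, background)
    for aoi, color in zip(aois, _COLORS * 10):
        c = aoi.coords
        if aoi.shape == "rectangle":
            ax.add_patch(Rectangle((c[0], c[1]), c[2] - c[0], c[3] - c[1],
                                   fill=False, color=color, lw=1.5))
            ax.annotate(aoi.name, (c[0], c[1]), color=color, fontsize=8)
        else:
            ax.add_patch(Ellipse((c[0], c[1]), 2 * c[2], 2 * c[3],
                                 fill=False, color=color, lw=1.5))
            ax.annotate(aoi.name, (c[0], c[1]), color=color, fontsize=8,
                        ha="center")
    if background is None:
        ax.relim()
        ax.autoscale_view()
        if unit_label:
            ax.set_xlabel(f"x ({unit_label})")
            ax.set_ylabel(f"y ({unit_label})")
    return _finish(fig, out)
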