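"""Merge, trim, and discard rules applied to event sets after classification.

Short gaps or bursts of imprecision can split one physiological fixation into
several classified ones; merging fixations that are close in space and time
(e.g. within 0.7° and 30–75 ms) undoes the split.  Trimming strips samples
near fixation boundaries that may belong to the flanking saccades, and the
drop rule removes physiologically implausible short fixations and, optionally,
tiny saccades.
"""

from __future__ import annotations

import numpy as np

from .events import Event, EventSet, FIXATION, SACCADE, event_from_samples

__all__ = ["merge_adjacent_fixations", "trim_fixations", "drop_fixations"]


def _merge_pair(a: Event, b: Event, rec) -> Event:
    """Merge fixation b into a: span grows, centroid is duration-weighted."""
    wa, wb = a.duration_ms, b.duration_ms
    merged = Event(
        kind=FIXATION, onset_ms=a.onset_ms, offset_ms=b.offset_ms,
        x=(a.x * wa + b.x * wb) / (wa + wb),
        y=(a.y * wa + b.y * wb) / (wa + wb),
        algorithm=a.algorithm,
        first_sample=a.first_sample if a.first_sample >= 0 else -1,
        last_sample=b.last_sample if b.last_sample >= 0 else -1,
        edge_truncated=a.edge_truncated or b.edge_truncated)
    if rec is not None and merged.first_sample >= 0 and merged.last_sample >= 0:
        # recompute rmsd/prop_missing over all constituent samples,
        # absorbed-gap samples included
        tmp = event_from_samples(rec, merged.first_sample, merged.last_sample,
                                 FIXATION, a.algorithm)
        merged.rmsd_deg = tmp.rmsd_deg
        merged.prop_missing = tmp.prop_missing
    else:
        gap = b.onset_ms - a.offset_ms
        span = merged.duration_ms
        covered = wa + wb
        # gap samples count as missing when samples are unavailable
        merged.prop_missing = ((a.prop_missing * wa + b.prop_missing * wb
                                + gap) / span if span > 0 else np.nan)
        merged.rmsd_deg = float(np.sqrt((a.rmsd_deg ** 2 * wa
                                         + b.rmsd_deg ** 2 * wb) / covered))
    return merged


def merge_adjacent_fixations(events: EventSet, max_dist_deg: float,
                             max_gap_ms: float) -> EventSet:
    """Merge consecutive fixations close in both space and time.

    Two consecutive fixations merge when their centroid distance is at most
    ``max_dist_deg`` and the gap between them at most ``max_gap_ms``.  The
    scan is chronological with immediate re-test, so chains merge against the
    running merged centroid; saccades wholly inside a merged span are
    removed.  The merged span includes the absorbed gap (span duration
    grows), while the summed within-fixation *sample* time is conserved.
    """
    if max_dist_deg < 0 or max_gap_ms < 0:
        raise ValueError("merge thresholds must be >= 0")
    rec = events.recording
    fixs = events.fixations()
    sacs = events.saccades()
    changed = True
    merged: list[Event] = fixs
    while changed:
        changed = False
        out: list[Event] = []
        for f in merged:
            if out:
                prev = out[-1]
                gap = f.onset_ms - prev.offset_ms
                dist = float(np.hypot(f.x - prev.x, f.y - prev.y))
                if gap <= max_gap_ms and dist <= max_dist_deg:
                    out[-1] = _merge_pair(prev, f, rec)
                    changed = True
                    continue
            out.append(f)
        merged = out
    spans = [(f.onset_ms, f.offset_ms) for f in merged]
    kept_sacs = [s for s in sacs
                 if not any(on <= s.onset_ms and s.offset_ms <= off
                            for on, off in spans)]
    return events.replace_events(merged + kept_sacs)


def trim_fixations(events: EventSet, rec=None, trim_ms: float = 0.0) -> EventSet:
    """Advance each fixation onset and recede its offset by ``trim_ms``.

    Fixations whose trimmed duration is not positive are dropped; centroid
    and RMSD are recomputed over the trimmed sample span when the recording
    is available.  Saccades are untouched.
    """
    if trim_ms < 0:
        raise ValueError("trim_ms must be >= 0")
    rec = rec if rec is not None else events.recording
    if trim_ms == 0:
        return events.replace_events(events.events)
    out: list[Event] = []
    for ev in events:
        if ev.kind != FIXATION:
            out.append(ev)
            continue
        on, off = ev.onset_ms + trim_ms, ev.offset_ms - trim_ms
        if off <= on:
            continue
        if rec is not None:
            idx = np.nonzero((rec.t >= on) & (rec.t < off))[0]
            if idx.size:
                new = event_from_samples(rec, int(idx[0]), int(idx[-1]),
                                         FIXATION, ev.algorithm)
                new.onset_ms, new.offset_ms = on, off
                new.edge_truncated = ev.edge_truncated
                out.append(new)
                continue
        new = Event(kind=FIXATION, onset_ms=on, offset_ms=off, x=ev.x, y=ev.y,
                    rmsd_deg=ev.rmsd_deg, prop_missing=ev.prop_missing,
                    algorithm=ev.algorithm, edge_truncated=ev.edge_truncated)
        out.append(new)
    return events.replace_events(out)


def drop_fixations(events: EventSet, min_duration_ms: float = 60.0,
                   max_prop_missing: float = 1.0,
                   min_saccade_ms: float | None = None,
                   min_saccade_amplitude_deg: float | None = None) -> EventSet:
    """Discard implausible events.

    Fixations shorter than ``min_duration_ms`` or with more than
    ``max_prop_missing`` originally-missing samples are removed.  When the
    saccade bounds are given, saccades shorter than ``min_saccade_ms`` or
    smaller than ``min_saccade_amplitude_deg`` are removed as well.
    """
    out: list[Event] = []
    for ev in events:
        if ev.kind == FIXATION:
            if ev.duration_ms < min_duration_ms:
                continue
            if np.isfinite(ev.prop_missing) and ev.prop_missing > max_prop_missing:
                continue
        else:
            if min_saccade_ms is not None and ev.duration_ms < min_saccade_ms:
                continue
            if (min_saccade_amplitude_deg is not None
                    and np.isfinite(ev.amplitude_deg)
                    and ev.amplitude_deg < min_saccade_amplitude_deg):
                continue
        out.append(ev)
    return events.replace_events(out)
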