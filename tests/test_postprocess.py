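"""Merge / trim / discard rules on classified events."""

import numpy as np
import pytest

from gazekit.events import Event, EventSet
from gazekit.postprocess import (drop_fixations, merge_adjacent_fixations,
                                 trim_fixations)


def fix(on, off, x=0.0, y=0.0, miss=0.0):
    return Event(kind="fixation", onset_ms=on, offset_ms=off, x=x, y=y,
                 rmsd_deg=0.1, prop_missing=miss, algorithm="test")


def sac(on, off):
    return Event(kind="saccade", onset_ms=on, offset_ms=off, algorithm="test")


def exhaustive_merge_oracle(fixations, max_dist, max_gap):
    """Repeated pairwise merging until no consecutive pair qualifies."""
    evs = [dict(on=f.onset_ms, off=f.offset_ms, x=f.x, y=f.y) for f in fixations]
    changed = True
    while changed:
        changed = False
        for i in range(len(evs) - 1):
            a, b = evs[i], evs[i + 1]
            gap = b["on"] - a["off"]
            dist = np.hypot(b["x"] - a["x"], b["y"] - a["y"])
            if gap <= max_gap and dist <= max_dist:
                wa, wb = a["off"] - a["on"], b["off"] - b["on"]
                evs[i] = dict(on=a["on"], off=b["off"],
                              x=(a["x"] * wa + b["x"] * wb) / (wa + wb),
                              y=(a["y"] * wa + b["y"] * wb) / (wa + wb))
                del evs[i + 1]
                changed = True
                break
    return evs


class TestMerge:
    def test_close_pair_merges(self):
        es = EventSet(events=[fix(0, 300, 0, 0), fix(340, 600, 0.3, 0)])
        out = merge_adjacent_fixations(es, 0.5, 75)
        assert len(out.fixations()) == 1
        f = out.fixations()[0]
        assert (f.onset_ms, f.offset_ms) == (0, 600)

    def test_distant_pair_untouched(self):
        es = EventSet(events=[fix(0, 300, 0, 0), fix(340, 600, 2.0, 0)])
        out = merge_adjacent_fixations(es, 0.5, 75)
        assert len(out.fixations()) == 2

    def test_two_spatial_clusters_merge_to_three(self):
        # six short fixations, two clusters around one saccade; within the
        # first cluster one inter-fixation gap exceeds the time criterion
        evs = [fix(0, 80, 0.1, 0), fix(120, 200, -0.1, 0),
               fix(450, 530, 0.0, 0),       # 250-ms gap: cannot merge back
               sac(540, 570),
               fix(580, 660, 5.0, 0), fix(700, 780, 5.1, 0),
               fix(820, 900, 4.9, 0)]
        es = EventSet(events=evs)
        out = merge_adjacent_fixations(es, 1.5, 200)
        oracle = exhaustive_merge_oracle(es.fixations(), 1.5, 200)
        assert len(out.fixations()) == len(oracle) == 3
        for got, exp in zip(out.fixations(), oracle):
            assert got.onset_ms == pytest.approx(exp["on"])
            assert got.offset_ms == pytest.approx(exp["off"])
            assert got.x == pytest.approx(exp["x"])

    def test_matches_oracle_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            t = 0.0
            evs = []
            for _i in range(n):
                t += rng.uniform(0, 120)
                d = rng.uniform(40, 300)
                evs.append(fix(t, t + d, rng.uniform(-2, 2), rng.uniform(-2, 2)))
                t += d
            es = EventSet(events=evs)
            out = merge_adjacent_fixations(es, 1.0, 100)
            oracle = exhaustive_merge_oracle(evs, 1.0, 100)
            assert len(out.fixations()) == len(oracle)
            for got, exp in zip(out.fixations(), oracle):
                assert got.onset_ms == pytest.approx(exp["on"])
                assert got.offset_ms == pytest.approx(exp["off"])

    def test_idempotent_and_count_monotone(self, rng):
        evs = []
        t = 0.0
        for _ in range(12):
            t += rng.uniform(0, 80)
            d = rng.uniform(40, 200)
            evs.append(fix(t, t + d, rng.uniform(-1, 1), 0))
            t += d
        es = EventSet(events=evs)
        once = merge_adjacent_fixations(es, 0.8, 90)
        twice = merge_adjacent_fixations(once, 0.8, 90)
        assert len(once.fixations()) <= len(es.fixations())
        assert [(f.onset_ms, f.offset_ms) for f in twice.fixations()] == \
               [(f.onset_ms, f.offset_ms) for f in once.fixations()]
        durs_before = [f.duration_ms for f in es.fixations()]
        durs_after = [f.duration_ms for f in once.fixations()]
        assert np.mean(durs_after) >= np.mean(durs_before)

    def test_sample_time_conserved_span_may_grow(self):
        from conftest import make_recording
        import gazekit as gk
        # two stationary stretches 0.2 deg apart, one-sample jump between
        rec = make_recording(
            np.concatenate([np.zeros(100), np.full(100, 0.2)]))
        es = gk.classify_ivt(rec, gk.IVTParams(merge_dist_deg=None,
                                               merge_gap_ms=None,
                                               min_saccade_ms=0,
                                               min_fixation_ms=50))
        assert len(es.fixations()) == 2
        sample_time_before = sum(f.n_samples for f in es.fixations())
        span_before = sum(f.duration_ms for f in es.fixations())
        out = merge_adjacent_fixations(es, 0.5, 75)
        assert len(out.fixations()) == 1
        assert sum(f.n_samples for f in out.fixations()) >= sample_time_before
        assert out.fixations()[0].duration_ms >= span_before

    def test_saccade_inside_merged_span_removed(self):
        es = EventSet(events=[fix(0, 300, 0, 0), sac(305, 335),
                              fix(340, 600, 0.2, 0)])
        out = merge_adjacent_fixations(es, 0.5, 75)
        assert len(out.saccades()) == 0

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            merge_adjacent_fixations(EventSet(), -1, 10)


class TestTrim:
    def test_zero_trim_is_identity(self):
        es = EventSet(events=[fix(0, 300), sac(300, 330)])
        out = trim_fixations(es, None, 0.0)
        assert [(e.kind, e.onset_ms, e.offset_ms) for e in out] == \
               [(e.kind, e.onset_ms, e.offset_ms) for e in es]

    def test_symmetric_trim(self):
        es = EventSet(events=[fix(100, 400, 1.0, 2.0)])
        out = trim_fixations(es, None, 20.0)
        f = out.fixations()[0]
        assert (f.onset_ms, f.offset_ms) == (120, 380)
        assert f.x == 1.0  # symmetric data: same centroid

    def test_overtrimmed_fixation_dropped(self):
        es = EventSet(events=[fix(0, 30)])
        assert len(trim_fixations(es, None, 20.0).fixations()) == 0

    def test_saccades_untouched(self):
        es = EventSet(events=[fix(0, 300), sac(300, 340)])
        out = trim_fixations(es, None, 10.0)
        assert out.saccades()[0].onset_ms == 300

    def test_trim_then_drop_equals_drop_on_trimmed(self):
        es = EventSet(events=[fix(0, 300), fix(350, 430), fix(500, 560)])
        a = drop_fixations(trim_fixations(es, None, 15.0), 60.0)
        kept = [f for f in trim_fixations(es, None, 15.0).fixations()
                if f.duration_ms >= 60.0]
        assert [(f.onset_ms, f.offset_ms) for f in a.fixations()] == \
               [(f.onset_ms, f.offset_ms) for f in kept]


class TestDrop:
    def test_duration_filter(self):
        es = EventSet(events=[fix(0, 40), fix(100, 180), fix(300, 500)])
        assert len(drop_fixations(es, 60).fixations()) == 2

    def test_missing_filter(self):
        es = EventSet(events=[fix(0, 100, miss=0.1), fix(200, 300, miss=0.9)])
        assert len(drop_fixations(es, 0, 0.5).fixations()) == 1

    def test_empty_set(self):
        assert len(drop_fixations(EventSet(), 60).events) == 0

    def test_saccade_amplitude_bound(self):
        small = Event(kind="saccade", onset_ms=0, offset_ms=20,
                      amplitude_deg=0.5)
        big = Event(kind="saccade", onset_ms=100, offset_ms=130,
                    amplitude_deg=4.0)
        es = EventSet(events=[small, big])
        out = drop_fixations(es, 0, 1.0, min_saccade_amplitude_deg=1.0)
        assert len(out.saccades()) == 1
        assert out.saccades()[0].amplitude_deg == 4.0
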