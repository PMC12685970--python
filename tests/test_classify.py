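"""The four event-classification algorithms against independent oracles."""

import warnings

import numpy as np
import pytest

import gazekit as gk
from gazekit.classify import (AdaptiveParams, I2MCParams, IDTParams,
                              IVTParams, adaptive_peak_threshold,
                              classify_adaptive, classify_i2mc, classify_idt,
                              classify_ivt, ivt_saccade_mask)
from gazekit.synthetic import SimSpec, simulate_gaze
from gazekit.velocity import compute_velocity

from conftest import make_recording, step_trace


def brute_force_ivt_labels(rec, threshold):
    """Per-sample saccade labels computed sample by sample from scratch."""
    labels = np.zeros(rec.n, dtype=bool)
    for i in range(1, rec.n):
        if rec.valid[i] and rec.valid[i - 1]:
            d = np.hypot(rec.x[i] - rec.x[i - 1], rec.y[i] - rec.y[i - 1])
            v = d / (rec.t[i] - rec.t[i - 1]) * 1000.0
            labels[i] = v > threshold
    return labels


def random_trace(rng, n=300, rate=1000.0, noise=0.1, loss=0.1):
    x = np.cumsum(rng.normal(0, 0.02, n)) + rng.normal(0, noise, n)
    y = np.cumsum(rng.normal(0, 0.02, n)) + rng.normal(0, noise, n)
    # sprinkle fast jumps
    for j in rng.integers(10, n - 10, 5):
        x[j:] += rng.choice([-1, 1]) * rng.uniform(1, 4)
    valid = rng.random(n) >= loss
    return make_recording(np.where(valid, x, np.nan),
                          np.where(valid, y, np.nan), rate_hz=rate,
                          valid=valid)


class TestIVT:
    def test_prefilter_labels_match_brute_force(self, rng):
        for _ in range(50):
            rate = rng.uniform(250, 1200)
            rec = random_trace(rng, n=200, rate=rate,
                               noise=rng.uniform(0, 0.5),
                               loss=rng.uniform(0, 0.3))
            thr = rng.uniform(10, 100)
            mask = ivt_saccade_mask(compute_velocity(rec), thr)
            assert np.array_equal(mask, brute_force_ivt_labels(rec, thr))

    def test_recovers_noise_free_plan(self):
        # three 300-ms fixations at 0, 6, 12 deg joined by 20-ms 300 deg/s ramps
        rec = step_trace([0.0, 6.0, 12.0], 300, ramp_samples=20)
        es = classify_ivt(rec, IVTParams(merge_dist_deg=None, merge_gap_ms=None))
        assert len(es.fixations()) == 3
        assert len(es.saccades()) == 2
        # brute-force segment boundaries from the label oracle
        labels = brute_force_ivt_labels(rec, 30.0)
        changes = np.nonzero(np.diff(labels.astype(int)) == -1)[0] + 1
        expected_onsets = [rec.t[0]] + [rec.t[i] for i in changes]
        for ev, t0 in zip(es.fixations(), expected_onsets):
            assert abs(ev.onset_ms - t0) <= 2.0

    def test_stationary_trace_single_fixation(self):
        rec = make_recording(np.full(200, 1.0))
        es = classify_ivt(rec)
        assert len(es.fixations()) == 1
        assert len(es.saccades()) == 0

    def test_missing_samples_filter_suppresses_gap_fixation(self):
        # fixation, fast jump into a 500-ms all-invalid gap, then a fixation
        x = np.concatenate([np.zeros(300),
                            np.linspace(0, 6, 20),
                            np.full(500, np.nan),
                            np.full(200, 6.0)])
        rec = make_recording(x)
        strict = classify_ivt(rec, IVTParams(merge_dist_deg=None,
                                             merge_gap_ms=None))
        loose = classify_ivt(rec, IVTParams(missing_samples_threshold=1.0,
                                            merge_dist_deg=None,
                                            merge_gap_ms=None))
        def covers_gap(es):
            return [f for f in es.fixations()
                    if f.onset_ms < 400 and f.offset_ms > 700]
        assert not covers_gap(strict)
        assert len(covers_gap(loose)) == 1

    def test_threshold_monotonicity(self, rng):
        rec = random_trace(rng)
        vel = compute_velocity(rec)
        counts = [ivt_saccade_mask(vel, thr).sum() for thr in (10, 30, 60, 120)]
        assert counts == sorted(counts, reverse=True)


class TestIDT:
    def test_tight_cluster_single_fixation_centroid_is_mean(self, rng):
        x = 1.0 + rng.uniform(-0.1, 0.1, 300)
        y = -2.0 + rng.uniform(-0.1, 0.1, 300)
        rec = make_recording(x, y)
        es = classify_idt(rec)
        assert len(es.fixations()) == 1
        f = es.fixations()[0]
        assert f.x == pytest.approx(x.mean())
        assert f.y == pytest.approx(y.mean())

    def test_linear_drift_split_matches_step_through_oracle(self):
        x = np.arange(400) * 0.01
        rec = make_recording(x)
        thr = 0.5
        # independent step-through of the greedy rule
        expected_splits = []
        start = 0
        csum, cnt = x[0], 1
        for j in range(1, len(x)):
            if abs(x[j] - csum / cnt) > thr:
                expected_splits.append((start, j - 1))
                start, csum, cnt = j, x[j], 1
            else:
                csum += x[j]
                cnt += 1
        expected_splits.append((start, len(x) - 1))
        es = classify_idt(rec, IDTParams(dispersion_threshold_deg=thr,
                                         min_fixation_ms=60))
        got = [(f.first_sample, f.last_sample) for f in es.fixations()]
        assert got == [s for s in expected_splits
                       if (s[1] - s[0] + 1) >= 60]

    def test_two_clusters_two_fixations(self):
        rec = step_trace([0.0, 5.0], 300, ramp_samples=1)
        es = classify_idt(rec)
        assert len(es.fixations()) == 2
        assert len(es.saccades()) == 1
        assert es.saccades()[0].kind == "saccade"
        assert np.isnan(es.saccades()[0].peak_velocity_dps)


class TestAdaptive:
    def test_constant_velocity_fixed_point(self):
        # constant speed c: the first update lands exactly on c (sd = 0)
        rec = make_recording(np.arange(500) * 0.01)  # 10 deg/s
        v = compute_velocity(rec).v
        pt, iters = adaptive_peak_threshold(v, 200.0, 6.0, 1.0)
        assert pt == pytest.approx(10.0, abs=1e-9)

    def test_matches_independent_iteration_oracle(self, rng):
        for _ in range(20):
            v = rng.normal(10, 2, 5000)
            for _b in range(3):
                j = rng.integers(100, 4800)
                v[j:j + 30] = 300.0
            pt, _ = adaptive_peak_threshold(v, 200.0, 6.0, 1.0)
            # independently coded direct fixed-point iteration
            ref = 200.0
            for _k in range(100):
                sub = v[v <= ref]
                new = sub.mean() + 6.0 * sub.std(ddof=1)
                if abs(new - ref) < 1.0:
                    ref = new
                    break
                ref = new
            assert pt == pytest.approx(ref, abs=1e-9)

    def test_lambda_monotonicity(self, rng):
        v = np.abs(rng.normal(10, 2, 10000))
        for j in rng.integers(100, 9800, 5):
            v[j:j + 30] = 300.0
        pt6, _ = adaptive_peak_threshold(v, 200.0, 6.0, 1.0)
        pt20, _ = adaptive_peak_threshold(v, 200.0, 20.0, 1.0)
        assert pt20 > pt6

    def test_emptying_subthreshold_set_warns_and_falls_back(self):
        v = np.full(100, 50.0)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            pt, _ = adaptive_peak_threshold(v, 10.0, 6.0, 1.0)
        assert pt == 10.0
        assert any("sub-threshold" in str(w.message) for w in caught)

    def test_detects_bursts_in_synthetic_trace(self):
        spec = SimSpec(rate_hz=1000,
                       fixations=[(0, 0, 300), (6, 0, 300), (0, 5, 300)],
                       noise_rms_deg=0.05, seed=5)
        rec, gt = simulate_gaze(spec)
        clean = gk.preprocess_gaze(rec)
        es = classify_adaptive(clean, AdaptiveParams(
            initial_peak_threshold_dps=100))
        assert len(es.fixations()) == 3
        assert len(es.saccades()) == 2


class TestI2MC:
    def test_noise_free_jump_two_fixations(self):
        rec = step_trace([0.0, 5.0], 400, ramp_samples=1)
        es = classify_i2mc(rec)
        fx = es.fixations()
        assert len(fx) == 2
        assert fx[0].x == pytest.approx(0.0, abs=1e-6)
        assert fx[1].x == pytest.approx(5.0, abs=1e-6)

    def test_noisy_lossy_jump_against_windowed_oracle(self, rng):
        from test_acceptance import brute_force_i2mc_transitions
        params = I2MCParams(downsample_factors=(2, 5),
                            edge_refine_sd=None)
        n = 400
        x = np.concatenate([np.zeros(200), np.full(200, 5.0)])
        x += rng.normal(0, 0.15, n)
        y = rng.normal(0, 0.15, n)
        valid = np.ones(n, bool)
        valid[200:] &= rng.random(200) >= 0.3
        rec = make_recording(np.where(valid, x, np.nan),
                             np.where(valid, y, np.nan),
                             rate_hz=500, valid=valid)
        from gazekit.classify import i2mc_transition_weights
        w = i2mc_transition_weights(rec, params)
        mine = w > w.mean() + params.weight_cutoff_sd * w.std()
        oracle = brute_force_i2mc_transitions(rec, params)
        t_mine = rec.t[mine]
        t_oracle = rec.t[oracle]
        assert len(t_mine) and len(t_oracle)
        # each oracle transition has a matching detection within one step
        for t0 in t_oracle:
            assert np.min(np.abs(t_mine - t0)) <= params.step_ms
        es = classify_i2mc(rec, I2MCParams(downsample_factors=(2, 5)))
        assert len(es.fixations()) == 2
        truth_onset = rec.t[200]
        assert abs(es.fixations()[1].onset_ms - truth_onset) <= params.step_ms

    def test_stationary_noise_single_fixation_most_seeds(self):
        good = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            rec = make_recording(r.normal(0, 0.1, 300),
                                 r.normal(0, 0.1, 300), rate_hz=500)
            es = classify_i2mc(rec, I2MCParams(downsample_factors=(2, 5)))
            good += len(es.fixations()) == 1
        assert good >= 38  # >= 95% of seeds

    def test_insufficient_data_raises(self):
        x = np.full(300, np.nan)
        rec = make_recording(x, valid=np.zeros(300, bool))
        with pytest.raises(Exception, match="insufficient"):
            classify_i2mc(rec)


class TestClassifierInvariants:
    @pytest.mark.parametrize("algo", ["ivt", "idt", "adaptive", "i2mc"])
    def test_events_ordered_disjoint_within_range(self, algo, rng):
        spec = SimSpec(rate_hz=500,
                       fixations=[(0, 0, 250), (4, 1, 200), (-2, 3, 250)],
                       noise_rms_deg=0.1, loss_prob=0.05,
                       seed=int(rng.integers(1 << 16)))
        rec, _ = simulate_gaze(spec)
        clean = gk.preprocess_gaze(rec)
        fn = dict(ivt=classify_ivt, idt=classify_idt,
                  adaptive=classify_adaptive, i2mc=classify_i2mc)[algo]
        es = fn(clean)
        dt = clean.median_dt_ms()
        for kind in ("fixation", "saccade"):
            evs = [e for e in es if e.kind == kind]
            for a, b in zip(evs, evs[1:]):
                assert b.onset_ms >= a.offset_ms
        for e in es:
            assert e.onset_ms >= clean.t[0]
            assert e.offset_ms <= clean.t[-1] + dt + 1e-9

    @pytest.mark.parametrize("algo", ["ivt", "idt", "adaptive", "i2mc"])
    def test_translation_invariance(self, algo):
        spec = SimSpec(rate_hz=500,
                       fixations=[(0, 0, 250), (5, 0, 250)],
                       noise_rms_deg=0.1, seed=7)
        rec, _ = simulate_gaze(spec)
        fn = dict(ivt=classify_ivt, idt=classify_idt,
                  adaptive=classify_adaptive, i2mc=classify_i2mc)[algo]
        shifted = rec.copy()
        shifted.x = shifted.x + 11.5
        shifted.y = shifted.y - 4.0
        a = fn(rec)
        b = fn(shifted)
        assert [(e.kind, e.onset_ms, e.offset_ms) for e in a] == \
               [(e.kind, e.onset_ms, e.offset_ms) for e in b]

    def test_min_duration_and_missing_rules_hold(self, rng):
        spec = SimSpec(rate_hz=500,
                       fixations=[(0, 0, 300), (5, 0, 80), (0, 4, 300)],
                       noise_rms_deg=0.2, loss_prob=0.2, seed=11)
        rec, _ = simulate_gaze(spec)
        clean = gk.preprocess_gaze(rec)
        params = IVTParams(merge_dist_deg=None, merge_gap_ms=None)
        es = classify_ivt(clean, params)
        for f in es.fixations():
            assert f.duration_ms >= params.min_fixation_ms
            sl = slice(f.first_sample, f.last_sample + 1)
            assert np.mean(~clean.valid[sl]) <= params.missing_samples_threshold
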