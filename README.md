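# gazekit

Fixation and saccade classification, data-quality metrics, area-of-interest
statistics, and visualization for screen-based eye-tracking data.

Most eye-tracking analyses rest on splitting the raw gaze stream into
**fixations** (periods of relatively stable gaze, typically 150–300 ms, when
visual information is processed) and **saccades** (the rapid ballistic
movements between them). The choice of event-classification algorithm and its
parameters can change study outcomes substantially — especially for noisy
recordings from infants or clinical populations — so a sound pipeline makes
that choice explicit, comparable, and reproducible. gazekit is for
researchers who want to run, compare, and validate the standard algorithms on
their own data, or to audit classification done by vendor software.

## What is implemented

Given per-sample timestamps and X/Y gaze coordinates (converted internally to
degrees of visual angle and milliseconds), gazekit provides:

* **Pre-processing** — linear interpolation over short invalid gaps
  (default ≤ 75 ms), anchored on the mean of a short margin of valid data on
  each side; centered moving-median or moving-average smoothing (default
  15 ms) that never bridges invalid runs; block-average downsampling.
* **Four event classifiers**, all returning the same event structure:
  * *I-VT*: samples with angular speed `v > v_T` (default 30°/s) are
    saccadic; `v_i = ‖p_i − p_{i−1}‖ / (t_i − t_{i−1})`.
  * *I-DT*: a fixation grows while each incoming sample stays within a
    dispersion radius (default 1°) of the running centroid.
  * *Adaptive velocity threshold*: the peak-saccade cutoff is iterated to the
    fixed point `PT = μ(v | v ≤ PT) + λ·σ(v | v ≤ PT)` (λ = 6), adapting to
    the noise level; onsets/offsets are found by walking out from each
    velocity peak against locally noise-calibrated thresholds.
  * *I2MC*: sliding 200-ms windows (also over 2×/5×/10× downsampled copies)
    are split by two-means clustering; samples where the cluster assignment
    switches accumulate weight, and fixations lie between high-weight
    transitions. Designed for noisy, gappy data.
* **Post-processing** — merging of fixations close in space and time,
  boundary trimming, and discard rules for implausible events.
* **Quality and agreement metrics** — proportion of data loss,
  sample-to-sample RMSD precision, and relative timing offset/deviation
  (RTO/RTD: mean and SD of onset/offset differences between fixations of two
  event streams matched one-to-one within a 15-ms margin).
* **AOI analysis** — rectangular/elliptical areas of interest with fixation
  counts, dwell time, entry latencies, and sample-level dwell proportions.
* **Simulation** — a scanpath generator (stable fixations + raised-cosine
  saccades + calibrated Gaussian noise + data loss) with per-sample ground
  truth, so every stage can be validated without any external recording.
* **Plots** — 2-D fixation overlays, coordinate/velocity time series,
  saccade velocity profiles, algorithm-quality panels, static and animated
  scanpaths.

## Worked example

```python
import gazekit as gk

# a 1200-Hz recording with known ground truth (six planned fixations)
rec, truth = gk.simulate_gaze(gk.fixture_spec("clean-1200Hz", seed=7))
clean = gk.preprocess_gaze(rec)

print(f"data loss: {gk.proportion_data_loss(rec):.3f}")
print(f"RMSD precision: {gk.rmsd_precision(rec):.3f} deg")

ivt = gk.classify_ivt(clean)
i2mc = gk.classify_i2mc(clean)
print(gk.summarize_algorithms([ivt, i2mc]).round(2).to_string(index=False))

cs = gk.compare_event_streams(ivt, i2mc)
print(f"RTO onset {cs.rto_onset_ms:+.2f} ms, RTD onset {cs.rtd_onset_ms:.2f} ms, "
      f"{cs.n_matched} matched")
```

prints

```
data loss: 0.000
RMSD precision: 0.127 deg
algorithm  n_fixations  mean_duration_ms  sd_duration_ms  mean_rmsd_deg  mean_prop_missing  total_fixation_time_ms
      ivt            6            241.11           42.02           0.02                0.0                 1446.67
     i2mc            6            236.81           43.17           0.01                0.0                 1420.83
RTO onset +1.67 ms, RTD onset 4.15 ms, 6 matched
```

Both classifiers recover the six planned fixations; their onsets agree to a
couple of milliseconds (RTO is the mean onset difference, RTD its standard
deviation), and the simulated 0.12° noise shows up directly in the RMSD
precision estimate. The same objects feed the AOI layer:

```python
aois = [gk.AOI("left", "rectangle", (-12, -6, 0, 6)),
        gk.AOI("right", "rectangle", (0.001, -6, 12, 6))]
print(gk.aoi_test(ivt, aois).round(1).to_string(index=False))
```

```
  aoi  n_fixations  total_fixation_time_ms  latency_first_inside_ms  overlapped  latency_first_outside_ms
 left            2                   520.8                      0.0       False                       NaN
right            4                   925.8                    279.2       False                       NaN
```

## Command line

Every stage is also a `gazekit` subcommand:

```bash
gazekit simulate --fixture noisy-lossy --seed 7 --out gaze.csv --truth truth.csv
gazekit preprocess --input gaze.csv --max-gap-ms 75 --smooth-window-ms 15 --output clean.csv
gazekit classify --all --input clean.csv --output events
gazekit compare --events-a events_ivt.csv --events-b events_i2mc.csv --margin-ms 15
gazekit run --config analysis.yaml      # full pipeline + manifest
```

`gazekit run` executes preprocess → classify → post-process → quality/AOI
summaries from a validated YAML/JSON config and writes a manifest with
parameters and SHA-256 hashes of every output.

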