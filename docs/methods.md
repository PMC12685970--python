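# Methods

This note documents the models and procedures gazekit implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that fix behavior in edge cases.

## Units, containers, and conventions

All analysis runs in degrees of visual angle (space) and milliseconds (time);
these are the units in which the standard thresholds are quoted (30°/s,
60 ms, 0.7°, …). Pixel or screen-proportion input is converted per axis by
exact arctangent about the screen center, `x_deg = atan(offset_cm /
distance_cm)`, which is monotone and invertible (round-trip error < 1e-9 px);
small-angle linearization is deliberately not used so the conversion has a
single fixed definition. Timestamps are re-based to 0 at the first sample.

A recording carries a per-sample `valid` flag and a separate `interpolated`
flag. Data-loss metrics honor the original recording: interpolated samples
count as missing there, while classifiers treat them as usable coordinates.

An event covering samples `i0..i1` has onset `t[i0]` and offset `t[i1+1]`
(last sample + one median interval at the recording edge), so durations are
positive, abutting events tile the timeline, and the simulator's ground
truth uses the identical convention. Velocity is assigned to the later
sample of each pair, making "first sample above threshold" an unambiguous
saccade onset.

## Pre-processing

* **Gap interpolation** (default `max_gap_ms = 75`): a maximal invalid run
  is bridged linearly when its duration (span plus one median interval) is
  at most the threshold and valid data flank it on both sides. Each anchor
  is the mean of the valid samples within `margin_ms = 10` adjacent to the
  gap — a short burst of noise next to a blink therefore cannot skew the
  bridge; 10 ms is short enough not to bias anchors within a fixation at
  120–1200 Hz. Boundary gaps and longer gaps are left untouched; original
  valid samples are never modified; the operation is idempotent.
* **Smoothing** (default 15-ms moving median): the window spans
  `round(w·rate/1000)` samples, forced odd, truncated at recording edges and
  at invalid runs (only the contiguous valid run containing the center
  contributes — padding would invent data). The median preserves saccade
  edges; the moving average (selectable) trades slight edge blur for
  stronger noise suppression.
* **Downsampling** is block-averaging (mean of the valid samples per block,
  timestamp of the block's first sample, valid iff any member is valid):
  it both lowers the rate and suppresses noise, which is exactly what the
  two-means classifier's coarse variants need.

## Event classification

**I-VT.** Saccade samples are exactly `{i : v_i > v_T}` (default 30°/s, the
conventional mid-range value; 20–40°/s appear in the literature). Undefined
velocities (first sample, or either neighbor invalid) are never saccadic and
break saccade runs — a saccade-like jump adjacent to a gap must not silently
extend an event. Saccade runs shorter than `min_saccade_ms = 10` dissolve
into the surrounding fixation context; fixations require
`min_fixation_ms = 60`; merging (0.5°, 75 ms) is applied by default.

**I-DT.** Greedy left-to-right growth: the candidate absorbs each incoming
valid sample while it lies within `dispersion_threshold_deg = 1.0` (about
half the foveal extent) of the running centroid of the included valid
samples; on violation the candidate is emitted if long enough and the scan
restarts at the violator. Invalid samples inside a candidate are tolerated
up to the missing-samples rule. Inter-fixation intervals are reported as
saccades without velocity metrics (dispersion algorithms do not measure
them), so AOI latency definitions work uniformly across classifiers.

**Adaptive velocity threshold.** The peak threshold iterates
`PT_{k+1} = μ(v | v ≤ PT_k) + λ·σ(v | v ≤ PT_k)` (inclusive comparison, so a
zero-variance trace converges in one update; sample SD with n−1; tolerance
1°/s; hard stop with an error after 100 iterations; an update that empties
the sub-threshold set falls back to the previous value with a warning).
λ = 6 is the conventional choice. Each maximal run with `v > PT` seeds a
saccade: the onset walk runs backwards until the speed drops below
`μ + 3σ` of the 40-ms noise window preceding the run, the offset walk
forwards until below `0.7·onset_threshold + 0.3·(μ + 3σ)` of the post-run
window (window statistics fall back to the global sub-threshold values when
a window holds fewer than two defined samples); overlapping saccades merge.
Saccades shorter than 12 ms are discarded; fixations require 40 ms.

*Bistability of the fixed point.* On very clean data the velocity
distribution is a near-zero noise mass plus heavy saccade tails, and the map
`PT ↦ μ+λσ` has two stable fixed points; from a high start the iteration can
converge above every saccade peak and detect nothing. The package default
start is 200°/s; for low-noise validation scenarios the scripts initialize
at 100°/s, the adaptive algorithm's original published default, from which
the iteration descends reliably to the noise-adapted threshold. Real
recordings with RMSD ≳ 0.1° at high rates have a single fixed point and are
insensitive to the start.

**I2MC.** For every window start (stride `step_ms = 20`, i.e. window/10, the
original convention) and every rate variant (native plus block-downsampled
by 2, 5, 10), windows with ≥ 50% valid samples (and ≥ 4 of them) are split
into two clusters by Lloyd iterations seeded deterministically with the
means of the window's first and second halves — a window containing a
transition is well separated, so the deterministic seed reproduces the same
split every run. Each sample where the assignment switches receives weight
`1/(switches in the window)`; a coarse-variant switch is attributed to the
first native sample of its block (the upsampled assignment changes there);
all other covered samples receive 0; the final weight is the mean over all
contributions. Transition samples exceed `mean + 2·sd` of the weights.

Two assembly details matter in practice and are deliberate choices:

* *Edge refinement* (`edge_refine_sd = 3`): a cluster switch localizes the
  transition at roughly the saccade midpoint, so the saccade's slow head and
  tail would otherwise be absorbed into the flanking fixations (≈ ±half a
  saccade duration of timing error). Candidate fixations are therefore
  peeled from each edge while the edge sample lies farther than 3 robust
  standard deviations (1.4826·MAD of distances from the candidate's median
  position, floored at 0.02°) — the refinement stage of the published
  two-means procedure. Set `edge_refine_sd=None` to disable.
* *Merge before the duration filter*: isolated weight spikes on noisy but
  stationary data can fragment a single fixation into sub-40-ms pieces; if
  those were duration-filtered first they could never reassemble. Candidates
  are merged (0.7°, 30 ms) first, then filtered by duration and the
  missing-samples rule. The spatial merge criterion prevents genuine
  saccade-separated fixations (amplitudes ≳ 1°) from merging.

**Missing-samples rule (all classifiers).** A fixation is rejected when more
than `missing_samples_threshold = 0.5` of its samples are invalid *at
classification time*. This targets the classic artifact of fixations
"detected" across long, uninterpolatable gaps, while recordings with heavy
but short-gapped loss (bridged by interpolation) still yield fixations.
Separately, every event reports `prop_missing`, the pre-interpolation
missing proportion, for quality control; the default threshold value is a
package choice, prominent in the configuration, since no canonical value is
established.

## Post-processing

Merging replaces consecutive fixations within `max_dist_deg` and
`max_gap_ms` by one fixation spanning first onset to last offset, with
duration-weighted centroid; the scan is chronological with immediate
re-test, so chains merge against the running merged centroid, and the pass
repeats until a fixed point (idempotence). The merged span includes absorbed
gaps — span duration grows — while the summed within-fixation *sample* time
is conserved; RMSD and missing proportions are recomputed from the
constituent samples via the sample-index ranges events carry. Saccades
wholly inside a merged span are removed. Trimming advances/recedes fixation
boundaries symmetrically (dropping non-positive remainders) and recomputes
centroid/RMSD on the trimmed span; the discard rule removes fixations below
a duration or above a missing-proportion bound, and optionally saccades
below a duration or amplitude bound (e.g. < 1°).

## Quality and agreement metrics

Data loss is the proportion of samples missing in the original recording.
Precision is the sample-to-sample root-mean-square displacement over
consecutive valid pairs: for i.i.d. per-axis noise with SD σ the expected
RMSD is 2σ (each axis difference has SD σ√2; two axes add in quadrature).

RTO/RTD: for each fixation of the reference stream in order, its match is
the *first unused* fixation of the comparison stream whose onset ≥ reference
onset − 15 ms and offset ≤ reference offset + 15 ms; matches are consumed so
one long fixation cannot match many. RTO is the mean and RTD the SD (n−1;
undefined below two matches) of the matched differences, signed as
comparison − reference (stated in output headers). The fixation-recovery F1
used in the robustness analyses matches detected to true fixations greedily,
one-to-one, requiring temporal overlap of at least half the shorter event.

## AOI analysis

Membership is centroid-based by default (strategies `any-sample` and
`majority-sample` are selectable). Totals accumulate clipped durations over
fixations overlapping the segment; latencies are measured from segment start
and only for fixations beginning inside the segment (a fixation already in
progress contributes clipped time but not latency). Overlapping AOIs are
allowed and flagged. Sample mode reports dwell proportions over valid
in-segment samples, with an explicit `outside` row so disjoint AOIs plus
outside sum to 1.

## The synthetic scanpath generator

The simulator emits the regimes the classifiers are designed for: alternating
stable fixations (150–300 ms is typical) and saccades with a raised-cosine
displacement profile — unimodal velocity, zero at both endpoints, peak
`A·π/(2D)` — whose duration follows the main-sequence-style rule
`D = 21 + 2.2·A` ms (rounded up to the sampling grid, ≥ 2 samples).
Within-fixation noise is isotropic Gaussian with per-axis σ = RMSD/2, so the
generator is calibrated directly in the same unit the precision metric
reports (0.12°, 0.20°, 0.36° emulate high-quality adult, moderate, and
low-quality clinical recordings). Data loss is injected as declared invalid
runs plus independent per-sample loss. Output is bit-reproducible given the
seed.

What it does **not** emulate — and hence what passing tests do not show
about real data: drift and microsaccades within fixations, smooth pursuit,
glissades, temporally correlated (1/f-like) noise, blink-adjacent velocity
artifacts, calibration offsets (spatial accuracy is out of scope
throughout), or binocular disparity. Conclusions about algorithm rankings on
real clinical data must come from real data; the simulator establishes
correctness of the implementations, not ecological validity.

## Validation scenarios and problem sizes

The test suite and `scripts/acceptance.py` use: a clean regime (10 fixations
of 150–300 ms, amplitudes 2–10°, 1000 Hz, 0.05° RMS noise, no loss),
pre-processed with gap interpolation plus a 7-ms moving average — at
1000 Hz a 7-sample window suppresses noise ≈ √7-fold while blurring event
boundaries by under 4 ms, appropriate when timing accuracy is the quantity
under test (the 15-ms default favors noise suppression instead); and a noisy
regime (8 fixations, 1200 Hz, 0.36° RMS, 60% random loss, 50 seeds) run
through the default pipeline. Oracle checks use 200 random traces (I-VT
labels), 50 velocity traces (adaptive fixed point, agreement to 1e-9), and
20 two-fixation traces at 500 Hz with 0.3° noise and 30% loss (two-means
transitions, agreement within one window step).

Under these conditions I-VT, the adaptive algorithm, and I2MC recover the
clean-regime plan exactly (10 fixations, onset errors ≤ ~2 ms, |RTO| < 2 ms,
RTD < 1 ms). **I-DT is systematically biased**: the greedy dispersion rule
absorbs the saccade portions that lie within 1° of each endpoint, extending
fixation offsets and advancing onsets by ~8–13 ms at these amplitudes and
profiles. This is intrinsic to dispersion-threshold classification — it
cannot sense motion slower than its radius — and is the documented reason
velocity-based algorithms are preferred when saccade timing matters; the
corresponding recovery test is expected to fail for I-DT and is left
failing rather than loosened. Boundary trimming exists precisely to
counteract this bias in applied work.

## Known limitations

* Monocular or pre-averaged binocular input only; per-eye analysis is out of
  scope (binocular column pairs are averaged at read time, invalid only when
  both eyes are).
* No smooth-pursuit, microsaccade, or glissade classification; no 3-D/glasses
  data; no spatial-accuracy estimation (requires known target positions).
* The adaptive algorithm's fixed-point start matters on unrealistically
  clean data (see above).
* AOI drawing is programmatic (JSON definitions plus an overlay renderer);
  there is no interactive GUI.
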