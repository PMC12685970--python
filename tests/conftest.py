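"""Shared fixtures and builders for the test suite.

All gaze data used by the tests are generated programmatically, either with
the tiny builders here or with the package's own scanpath simulator.
"""

from __future__ import annotations

import numpy as np
import pytest

from gazekit.io import GazeRecording, ScreenGeometry


def make_recording(x, y=None, *, rate_hz=1000.0, valid=None, unit="deg",
                   geometry=None, t=None) -> GazeRecording:
    """Build a recording from coordinate arrays on a regular grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float) if y is not None else np.zeros_like(x)
    if t is None:
        t = np.arange(len(x)) * 1000.0 / rate_hz
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    valid = np.asarray(valid, dtype=bool)
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeRecording(t=np.asarray(t, dtype=float), x=x, y=y, valid=valid,
                         unit=unit, geometry=geometry, rate_hz=rate_hz)


def step_trace(positions, dwell_samples, *, rate_hz=1000.0, ramp_samples=0):
    """Piecewise-constant x-trace visiting ``positions``; optional linear
    ramps of ``ramp_samples`` between them."""
    xs = []
    for i, p in enumerate(positions):
        xs.extend([p] * dwell_samples)
        if ramp_samples and i + 1 < len(positions):
            nxt = positions[i + 1]
            xs.extend(np.linspace(p, nxt, ramp_samples + 2)[1:-1])
    return make_recording(xs, rate_hz=rate_hz)


@pytest.fixture
def geometry():
    return ScreenGeometry(distance_cm=65.0, screen_width_cm=52.7,
                          screen_height_cm=29.6, res_x_px=1920, res_y_px=1080)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
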