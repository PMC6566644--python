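"""Shared fixtures and brute-force oracles for the test suite.

The oracles recompute windowed statistics by direct per-window summation
(O(n*w)), independent of the cumulative-sum implementation they check.
"""

import numpy as np
import pytest

from xcski.preprocess import window_halfwidth
from xcski.synthetic import TechniqueMotifSpec, generate_session


def brute_window(x, i, dt, fs):
    h = window_halfwidth(dt, fs)
    n = len(x)
    return x[max(0, i - h):min(n - 1, i + h) + 1]


def brute_sliding_variance(x, dt, fs):
    """Direct-summation centered windowed variance (population form)."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x))
    for i in range(len(x)):
        w = brute_window(x, i, dt, fs)
        out[i] = np.mean((w - w.mean()) ** 2)
    return out


def brute_sliding_correlation(x, y, dt, fs):
    """Direct-summation windowed Pearson correlation; 0 for degenerate
    windows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty(len(x))
    for i in range(len(x)):
        wx = brute_window(x, i, dt, fs) * 1.0
        wy = brute_window(y, i, dt, fs) * 1.0
        wx = wx - wx.mean()
        wy = wy - wy.mean()
        vx = np.mean(wx ** 2)
        vy = np.mean(wy ** 2)
        if vx < 1e-12 or vy < 1e-12:
            out[i] = 0.0
        else:
            out[i] = np.mean(wx * wy) / np.sqrt(vx * vy)
    return out


# A window of 51 samples (dt=2.5 s at 20 Hz) spans exactly 3 periods of
# this frequency, so sinusoid window statistics take their closed-form
# values exactly at interior samples.
FS = 20.0
DT_EXACT = 2.5
F_EXACT = FS * 3 / 51


@pytest.fixture(scope="session")
def seven_segment_session():
    """Seeded session with all six techniques plus a quiet stretch, at the
    default (noisy) generator conditions."""
    specs = [TechniqueMotifSpec.for_technique(t, duration=60.0, seed=11)
             for t in ["DIA", "DP", "DK", "DPrK", "rK", "HRB", "noTech"]]
    return generate_session(specs, fs=FS, seed=11, validate=False)


@pytest.fixture(scope="session")
def clean_dia_segment():
    spec = TechniqueMotifSpec.for_technique(
        "DIA", duration=30.0, seed=3, noise_sd_gyro=0.0, noise_sd_accel=0.0)
    return generate_session([spec], fs=FS, validate=False)


@pytest.fixture(scope="session")
def clean_dp_segment():
    spec = TechniqueMotifSpec.for_technique(
        "DP", duration=30.0, seed=4, noise_sd_gyro=0.0, noise_sd_accel=0.0)
    return generate_session([spec], fs=FS, validate=False)
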