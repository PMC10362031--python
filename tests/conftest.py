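"""Shared fixtures and independent oracles used across the suite."""

import numpy as np
import pytest

from scgvision import make_scg_waveform, render_video
from scgvision.signals import UniformSignal


def brute_force_dtw(a, b):
    """Exhaustive-path DTW oracle: minimal accumulated |a_i - b_j| over all
    monotone paths with steps (1,0), (0,1), (1,1), by plain recursion with
    memoization. Independent of the banded dynamic program under test;
    only usable for short series."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        best = np.inf
        if i > 0 and j > 0:
            best = min(best, d(i - 1, j - 1))
        if i > 0:
            best = min(best, d(i - 1, j))
        if j > 0:
            best = min(best, d(i, j - 1))
        return cost + best

    return d(len(a) - 1, len(b) - 1)


@pytest.fixture(scope="session")
def sinusoid_scene():
    """Rendered scene with pure 0.3 px sinusoidal x-motion at 1.2 Hz,
    10 s at 60 fps — the renderer's prescribed displacement is the ground
    truth for tracker accuracy."""
    fs = 600.0
    t = np.arange(int(10.0 * fs)) / fs
    scale = 0.1  # mm per px
    wx = UniformSignal(0.3 * scale * np.sin(2 * np.pi * 1.2 * t), fs, units="mm")
    wy = UniformSignal(np.zeros_like(t), fs, units="mm")
    return render_video(wx, wy, scale_mm_per_px=scale, fps=60.0,
                        texture_seed=7)


@pytest.fixture(scope="session")
def cardiac_scene():
    """Scene driven by the cardiac-like waveform at 72 bpm (modest rate,
    for tests that only need realistic motion, not full references)."""
    fs = 1000.0
    wx = make_scg_waveform(72, 8.0, fs, seed=11)
    wy = make_scg_waveform(72, 8.0, fs, seed=12)
    return render_video(wx, wy, scale_mm_per_px=0.1, fps=60.0,
                        texture_seed=3)
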