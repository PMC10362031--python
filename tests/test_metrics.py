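"""Validation metrics: correlation, banded DTW and the similarity index,
lag estimation, wavelet coherence, Bland-Altman."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_dtw
from scgvision.errors import (
    InsufficientPairsError,
    UndefinedCorrelationError,
    UndefinedLagError,
    ZeroNormalizerError,
)
from scgvision.metrics import (
    bland_altman,
    dtw_alignment,
    estimate_lag,
    pearson_r,
    similarity_index,
    wavelet_coherence,
)
from scgvision.signals import UniformSignal


class TestPearson:
    def test_positive_affine_invariance(self):
        a = np.random.default_rng(0).standard_normal(50)
        assert pearson_r(a, 2 * a + 3) == pytest.approx(1.0)

    def test_sign_flip(self):
        a = np.random.default_rng(1).standard_normal(50)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_constant_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestDtw:
    def test_identity_alignment(self):
        a = np.sin(np.linspace(0, 3, 40))
        res = dtw_alignment(a, a, 0.05)
        assert res.distance == 0.0
        assert np.array_equal(res.path, np.stack([np.arange(40)] * 2, axis=1))

    def test_small_example_matches_enumeration(self):
        a, b = [0.0, 0.0, 1.0], [0.0, 1.0]
        assert brute_force_dtw(a, b) == 0.0
        assert dtw_alignment(a, b, band_fraction=None).distance == 0.0

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            na, nb = rng.integers(2, 13, size=2)
            a = rng.uniform(-2, 2, na)
            b = rng.uniform(-2, 2, nb)
            got = dtw_alignment(a, b, band_fraction=None).distance
            assert got == pytest.approx(brute_force_dtw(tuple(a), tuple(b)),
                                        abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        assert (dtw_alignment(a, b, 0.1).distance
                == pytest.approx(dtw_alignment(b, a, 0.1).distance))

    def test_wider_band_never_increases_distance(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(60)
        b = rng.standard_normal(60)
        prev = np.inf
        for frac in (0.02, 0.05, 0.1, 0.3, None):
            d = dtw_alignment(a, b, frac).distance
            assert d <= prev + 1e-12
            prev = d

    def test_path_stays_in_band(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(80)
        b = rng.standard_normal(100)
        frac = 0.05
        res = dtw_alignment(a, b, frac)
        width = np.ceil(frac * 100)
        slope = (len(b) - 1) / (len(a) - 1)
        for i, j in res.path:
            assert abs(i * slope - j) <= width + 1e-9
        assert tuple(res.path[0]) == (0, 0)
        assert tuple(res.path[-1]) == (79, 99)
        steps = np.diff(res.path, axis=0)
        assert set(map(tuple, steps)) <= {(1, 0), (0, 1), (1, 1)}


class TestSimilarityIndex:
    def test_identical_waveforms(self):
        g = np.sin(np.linspace(0, 6, 200))
        score = similarity_index(g, g)
        assert score.s == 1.0

    def test_plug_in_example(self):
        # max|gold| = 2 and n_c = 4 give M = 8; the vision series differs in
        # one sample by 0.8, and enumeration confirms D = 0.8, so S = 0.9
        gold = np.array([2.0, 1.0, 0.0, -1.0])
        vision = np.array([2.0, 1.0, 0.8, -1.0])
        assert brute_force_dtw(gold, vision) == pytest.approx(0.8)
        score = similarity_index(gold, vision, band_fraction=None)
        assert score.m == pytest.approx(8.0)
        assert score.d == pytest.approx(0.8)
        assert score.s == pytest.approx(0.9, abs=1e-12)

    def test_scale_consistency(self):
        rng = np.random.default_rng(6)
        g = rng.standard_normal(100)
        v = g + 0.1 * rng.standard_normal(100)
        s1 = similarity_index(g, v).s
        s2 = similarity_index(5.0 * g, 5.0 * v).s
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_zero_gold_raises(self):
        with pytest.raises(ZeroNormalizerError):
            similarity_index(np.zeros(10), np.ones(10))

    def test_out_of_range_flagged_not_clamped(self):
        gold = np.array([0.1, 0.1, 0.1, 0.1])
        vision = np.array([5.0, -5.0, 5.0, -5.0])
        score = similarity_index(gold, vision, band_fraction=None)
        assert score.s < 0.0
        assert not score.in_range


class TestEstimateLag:
    @staticmethod
    def _sig(x, fs):
        return UniformSignal(x, fs)

    def test_constructed_delay(self):
        fs = 5000.0
        t = np.arange(int(4 * fs)) / fs
        a = np.sin(2 * np.pi * 7 * t) * np.exp(-((t - 2) ** 2))
        shift = int(0.050 * fs)
        b = np.roll(a, shift)
        lag = estimate_lag(self._sig(a, fs), self._sig(b, fs), max_lag=0.2)
        assert lag == pytest.approx(0.050, abs=1e-9)

    def test_zero_lag_for_identical(self):
        fs = 1000.0
        a = np.random.default_rng(0).standard_normal(int(2 * fs))
        assert estimate_lag(self._sig(a, fs), self._sig(a, fs), 0.2) == 0.0

    def test_noisy_delay_recovered(self):
        fs = 5000.0
        rng = np.random.default_rng(1)
        t = np.arange(int(6 * fs)) / fs
        a = np.sin(2 * np.pi * 5 * t) + 0.5 * np.sin(2 * np.pi * 13 * t)
        b = np.roll(a, int(0.050 * fs))
        snr_amp = 10 ** (-10 / 20) * np.sqrt(np.mean(a**2))
        b = b + rng.standard_normal(len(b)) * snr_amp
        lag = estimate_lag(self._sig(a, fs), self._sig(b, fs), 0.2)
        assert lag == pytest.approx(0.050, abs=0.002)

    def test_constant_undefined(self):
        fs = 100.0
        with pytest.raises(UndefinedLagError):
            estimate_lag(self._sig(np.ones(500), fs),
                         self._sig(np.arange(500.0), fs), 0.5)


class TestWaveletCoherence:
    def test_self_coherence_is_one(self):
        fs = 100.0
        x = np.random.default_rng(2).standard_normal(int(10 * fs))
        coh = wavelet_coherence(UniformSignal(x, fs), UniformSignal(x, fs))
        assert np.max(np.abs(coh.coherence - 1.0)) < 1e-6

    def test_amplitude_scaling_invariance(self):
        fs = 100.0
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(8 * fs))
        y = rng.standard_normal(int(8 * fs))
        c1 = wavelet_coherence(UniformSignal(x, fs), UniformSignal(y, fs))
        c2 = wavelet_coherence(UniformSignal(x, fs), UniformSignal(3 * y, fs))
        assert np.allclose(c1.coherence, c2.coherence, atol=1e-9)

    def test_bounded_zero_one(self):
        fs = 80.0
        rng = np.random.default_rng(4)
        for _ in range(3):
            x = rng.standard_normal(int(6 * fs))
            y = 0.5 * x + rng.standard_normal(int(6 * fs))
            coh = wavelet_coherence(UniformSignal(x, fs), UniformSignal(y, fs))
            assert coh.coherence.min() >= -1e-6
            assert coh.coherence.max() <= 1.0 + 1e-6

    def test_independent_noise_low_coherence(self):
        fs = 100.0
        means = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(int(60 * fs))
            b = rng.standard_normal(int(60 * fs))
            coh = wavelet_coherence(UniformSignal(a, fs), UniformSignal(b, fs))
            means.append(coh.coherence[coh.inside_coi()].mean())
        assert np.mean(means) < 0.5

    def test_coi_monotone_toward_edges(self):
        fs = 100.0
        x = np.random.default_rng(5).standard_normal(int(8 * fs))
        coh = wavelet_coherence(UniformSignal(x, fs), UniformSignal(x, fs))
        n = len(coh.coi)
        first_half = coh.coi[:n // 2]
        assert np.all(np.diff(first_half) <= 1e-12)   # relaxes away from edge


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([70.0, 75.0, 80.0])
        stats = bland_altman(a, a)
        assert stats.bias == 0.0
        assert stats.loa_low == 0.0 and stats.loa_high == 0.0

    def test_constant_offset(self):
        a = np.array([70.0, 75.0, 80.0])
        stats = bland_altman(a, a - 2.0)
        assert stats.bias == pytest.approx(2.0)
        assert stats.loa_low == pytest.approx(2.0)
        assert stats.loa_high == pytest.approx(2.0)

    def test_hand_computed_two_pairs(self):
        # d = (-2, +2): bias 0, sample SD = 2.828, limits = -/+ 5.543
        stats = bland_altman([70.0, 80.0], [72.0, 78.0])
        assert stats.bias == pytest.approx(0.0, abs=1e-12)
        assert stats.loa_low == pytest.approx(-5.543, abs=1e-3)
        assert stats.loa_high == pytest.approx(5.543, abs=1e-3)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20))
    def test_antisymmetric_bias(self, vals):
        a = np.asarray(vals)
        b = np.linspace(0, 1, len(a))
        assert bland_altman(a, b).bias == pytest.approx(-bland_altman(b, a).bias,
                                                        abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientPairsError):
            bland_altman([1.0], [2.0])
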