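import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from affectflight.features import (
    ENTROPY_FLOOR,
    FeatureConfig,
    WaveletConfig,
    basic_stats,
    build_feature_matrix,
    count_peaks,
    differential_entropy,
    extract_all,
    poincare_descriptors,
    rr_from_hr,
    sample_range,
    wavelet_features,
)


class TestBasicStats:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([3, 3, 3], {"MN": 3, "MD": 3, "STD": 0, "VAR": 0, "RMS": 3}),
            ([-1, 1], {"MN": 0, "MD": 0, "RMS": 1}),
            ([1, 2, 3, 4], {"MN": 2.5, "MD": 2.5, "VAR": 1.25}),
        ],
    )
    def test_hand_computed(self, values, expected):
        out = basic_stats(np.array(values, dtype=float))
        for k, v in expected.items():
            assert out[k] == pytest.approx(v)

    def test_var_is_std_squared(self, rng):
        out = basic_stats(rng.normal(0, 3, 100))
        assert out["VAR"] == pytest.approx(out["STD"] ** 2, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            basic_stats(np.array([]))


class TestDifferentialEntropy:
    def test_uniform_closed_form(self, rng):
        h = differential_entropy(rng.uniform(0, 1, 10_000))
        assert abs(h) < 0.05  # h(U[0,1]) = 0

    def test_gaussian_closed_form(self, rng):
        h = differential_entropy(rng.normal(0, 1, 10_000))
        assert h == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=0.05)

    def test_scaling_law(self, rng):
        """h(cX) = h(X) + ln c for c > 0."""
        x = rng.normal(0, 1, 10_000)
        c = 3.7
        assert differential_entropy(c * x) == pytest.approx(
            differential_entropy(x) + np.log(c), abs=0.05
        )

    def test_constant_input_hits_floor(self):
        assert differential_entropy(np.full(100, 2.0)) == ENTROPY_FLOOR

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            differential_entropy(np.arange(5.0))


class TestSampleRange:
    def test_extrema_and_endpoint_modes(self):
        x = np.array([1.0, 5.0, 2.0])
        assert sample_range(x, "extrema") == 4.0
        assert sample_range(x, "endpoints") == 1.0

    def test_constant_zero_both_modes(self):
        x = np.full(5, 2.0)
        assert sample_range(x, "extrema") == 0.0
        assert sample_range(x, "endpoints") == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            sample_range(np.array([1.0]))


class TestCountPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        assert count_peaks(np.linspace(0, 1, 100), fs=10.0) == 0.0

    def test_constructed_peak_rate(self):
        """5 prominent phasic bumps over 10 s → 0.5 peaks/s."""
        fs = 16.0
        t = np.arange(int(10 * fs)) / fs
        x = np.zeros_like(t)
        for t0 in (1.0, 3.0, 5.0, 7.0, 9.0):
            x += np.where(t >= t0, 0.5 * np.exp(-(t - t0) / 0.5), 0.0)
        assert count_peaks(x, fs=fs, prominence=0.1) == pytest.approx(0.5)

    def test_rate_stable_under_window_doubling(self, rng):
        fs = 16.0
        x = np.sin(2 * np.pi * 0.5 * np.arange(int(20 * fs)) / fs)
        r1 = count_peaks(x[: int(10 * fs)], fs, prominence=0.5)
        r2 = count_peaks(x, fs, prominence=0.5)
        assert abs(r1 - r2) <= 1.0 / 10.0  # ± one boundary peak

    def test_nonpositive_prominence_rejected(self):
        with pytest.raises(ValueError):
            count_peaks(np.zeros(10), fs=1.0, prominence=0.0)


from _oracles import poincare_bruteforce, reference_dwt_cascade


class TestWaveletFeatures:
    def test_zero_and_constant_signals(self):
        cfg = WaveletConfig()
        z = wavelet_features(np.zeros(1000), cfg)
        assert z["WAC"] == 0.0 and z["WDC"] == 0.0
        c = wavelet_features(np.full(1000, 4.2), cfg)
        assert c["WDC"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_bruteforce_convolution_dwt(self, rng):
        """Oracle: direct convolution/downsample cascade reproduces the
        level-4 sym7 approximation and detail means to 1e-8."""
        x = rng.normal(0, 1, 2000)
        w = pywt.Wavelet("sym7")
        a, d = reference_dwt_cascade(x, np.array(w.dec_lo), np.array(w.dec_hi), 4)
        got = wavelet_features(x, WaveletConfig(level=4))
        assert got["WAC"] == pytest.approx(a.mean(), abs=1e-8)
        assert got["WDC"] == pytest.approx(d.mean(), abs=1e-8)

    def test_too_short_window_names_minimum(self):
        with pytest.raises(ValueError, match="needs >="):
            wavelet_features(np.zeros(20), WaveletConfig(level=4))


class TestRRFromHR:
    @pytest.mark.parametrize("bpm, rr", [(60.0, 1000.0), (75.0, 800.0)])
    def test_scalar_conversions(self, bpm, rr):
        assert rr_from_hr(np.array([bpm]))[0] == pytest.approx(rr)

    def test_vector_conversion(self):
        assert np.allclose(rr_from_hr(np.array([60.0, 120.0])), [1000.0, 500.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rr_from_hr(np.array([60.0, 0.0]))


class TestPoincare:
    def test_constant_rr(self):
        pc = poincare_descriptors(np.array([800.0, 800.0, 800.0]))
        assert pc.sd1 == 0.0 and pc.sd2 == 0.0 and pc.ellipse_area == 0.0
        assert pc.centroid_norm == pytest.approx(800 * np.sqrt(2), abs=1e-6)

    def test_alternating_rr_is_pure_short_term(self):
        pc = poincare_descriptors(np.array([600.0, 800.0, 600.0]))
        assert pc.sd1 == pytest.approx(100 * np.sqrt(2), abs=1e-9)
        assert pc.sd2 == pytest.approx(0.0, abs=1e-9)
        assert pc.ellipse_area == pytest.approx(0.0, abs=1e-6)

    def test_matches_bruteforce_on_random_series(self, rng):
        for _ in range(100):
            rr = rng.uniform(500, 1200, rng.integers(3, 50))
            pc = poincare_descriptors(rr)
            sd1, sd2, cn, area = poincare_bruteforce(rr)
            assert pc.sd1 == pytest.approx(sd1, abs=1e-9)
            assert pc.sd2 == pytest.approx(sd2, abs=1e-9)
            assert pc.centroid_norm == pytest.approx(cn, abs=1e-9)
            assert pc.ellipse_area == pytest.approx(area, abs=1e-9)

    def test_area_identity(self, rng):
        rr = rng.uniform(600, 1000, 30)
        pc = poincare_descriptors(rr)
        assert pc.ellipse_area == pytest.approx(np.pi * pc.sd1 * pc.sd2, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            poincare_descriptors(np.array([800.0, 810.0]))


class TestBlockStructure:
    def test_block_lengths(self, windowed_samples):
        cfg = FeatureConfig()
        vec = extract_all(windowed_samples[0], cfg)
        hr = [k for k in vec if k.startswith("hr_")]
        gsr = [k for k in vec if k.startswith("gsr_")]
        eeg = [k for k in vec if k.startswith("eeg_")]
        assert len(hr) == 11
        assert len(gsr) == 7
        assert len(eeg) == 72
        assert len(vec) == 90

    def test_extraction_deterministic(self, windowed_samples):
        a = extract_all(windowed_samples[3])
        b = extract_all(windowed_samples[3])
        assert a == b

    def test_feature_matrix_shape_and_names(self, windowed_samples):
        fm = build_feature_matrix(windowed_samples)
        assert fm.X.shape == (len(windowed_samples), 90)
        assert fm.y.shape == (len(windowed_samples), 5)
        assert not fm.X.isna().any().any()
        assert fm.blocks[:2] == ["hr", "gsr"] and len(fm.blocks) == 10

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-50, 50))
    def test_shift_invariance_where_expected(self, seed, shift):
        x = np.random.default_rng(seed).normal(0, 2, 64)
        a, b = basic_stats(x), basic_stats(x + shift)
        assert b["STD"] == pytest.approx(a["STD"], rel=1e-9, abs=1e-9)
        assert b["VAR"] == pytest.approx(a["VAR"], rel=1e-9, abs=1e-9)
        assert sample_range(x + shift) == pytest.approx(sample_range(x), abs=1e-9)
        if abs(shift) > 1e-6:
            assert b["MN"] != pytest.approx(a["MN"], abs=1e-12)
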