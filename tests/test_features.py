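"""Feature extraction against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from seismocrab import (
    extract_features,
    log_energy,
    merged_spectrum,
    normalized_energy,
    peak_amplitude,
    peak_frequency,
    summed_energy,
)
from seismocrab.features import spectrum_magnitudes
from seismocrab.windowing import SignalWindow

FS = 1612.0


def dft_oracle(x):
    """Direct O(N²) discrete Fourier transform magnitudes (one-sided)."""
    n = len(x)
    k = np.arange(n // 2 + 1)
    mags = np.empty(len(k))
    for i, kk in enumerate(k):
        re = sum(x[j] * math.cos(-2 * math.pi * kk * j / n) for j in range(n))
        im = sum(x[j] * math.sin(-2 * math.pi * kk * j / n) for j in range(n))
        mags[i] = math.hypot(re, im)
    return mags


class TestAmplitudeAndEnergy:
    def test_peak_is_sign_blind(self):
        assert peak_amplitude([0.0, -3e-5, 2e-5]) == pytest.approx(3e-5)

    def test_zero_segment(self):
        assert peak_amplitude(np.zeros(10)) == 0.0
        assert normalized_energy(np.zeros(10)) == 0.0

    def test_constant_window_energy(self):
        # 645 unit samples → sum(v²)/2 = 322.5
        assert normalized_energy(np.ones(645)) == pytest.approx(322.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            peak_amplitude(np.array([]))
        with pytest.raises(ValueError):
            normalized_energy(np.array([]))

    def test_brute_force_oracle(self, rng):
        v = rng.normal(scale=1e-5, size=645)
        oracle = sum(float(x) * float(x) for x in v) / 2.0
        assert normalized_energy(v) == pytest.approx(oracle, rel=1e-12)
        assert peak_amplitude(v) == pytest.approx(max(abs(float(x)) for x in v), rel=0)

    @given(
        hnp.arrays(np.float64, st.integers(1, 200),
                   elements=st.floats(-1e-4, 1e-4)),
        hnp.arrays(np.float64, st.integers(1, 200),
                   elements=st.floats(-1e-4, 1e-4)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_energy_additive_over_concatenation(self, a, b):
        total = normalized_energy(np.concatenate([a, b]))
        assert total == pytest.approx(
            normalized_energy(a) + normalized_energy(b), rel=1e-9, abs=1e-30
        )

    @given(
        hnp.arrays(np.float64, 64, elements=st.floats(-1e-4, 1e-4)),
        st.floats(min_value=-10.0, max_value=10.0).filter(lambda c: abs(c) >= 1e-3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scaling_laws(self, v, c):
        if peak_amplitude(v) == 0:
            return
        assert peak_amplitude(c * v) == pytest.approx(abs(c) * peak_amplitude(v), rel=1e-12)
        assert normalized_energy(c * v) == pytest.approx(
            c * c * normalized_energy(v), rel=1e-12
        )

    def test_summed_energy_over_close_pair(self, rng):
        low = rng.normal(size=645)
        high = rng.normal(size=645)
        w = SignalWindow(
            segments={"close_low": low, "close_high": high}, t0=0, t1=0.4, fs=FS
        )
        assert summed_energy(w) == pytest.approx(
            normalized_energy(low) + normalized_energy(high), rel=1e-12
        )
        w_zero_low = SignalWindow(
            segments={"close_low": np.zeros(645), "close_high": high},
            t0=0, t1=0.4, fs=FS,
        )
        assert summed_energy(w_zero_low) == pytest.approx(normalized_energy(high))

    def test_log_energy(self):
        assert log_energy(math.e) == pytest.approx(1.0)
        assert log_energy(1.0) == 0.0
        assert log_energy(322.5) == pytest.approx(math.log(322.5), rel=1e-12)
        with pytest.raises(ValueError):
            log_energy(0.0)


class TestMergedSpectrum:
    def tone(self, f, n=645, amp=1.0, fs=FS):
        return amp * np.sin(2 * np.pi * f * np.arange(n) / fs)

    def test_low_band_tone(self):
        spec = merged_spectrum(self.tone(50.0), self.tone(50.0), FS)
        pf = peak_frequency(spec)
        assert abs(pf - 50.0) <= FS / 645  # within one bin
        assert spec.source[np.argmax(spec.magnitudes)] == "low"

    def test_high_band_tone(self):
        spec = merged_spectrum(self.tone(300.0), self.tone(300.0), FS)
        pf = peak_frequency(spec)
        assert abs(pf - 300.0) <= FS / 645
        assert spec.source[np.argmax(spec.magnitudes)] == "high"

    def test_two_tone_dominance(self):
        low = self.tone(80.0, amp=2.0) + self.tone(300.0, amp=1.0)
        spec = merged_spectrum(low, low, FS)
        assert abs(peak_frequency(spec) - 80.0) <= FS / 645

    def test_flat_spectrum_tie_goes_to_lowest_bin(self):
        spec = merged_spectrum(np.zeros(645), np.zeros(645), FS)
        # all-zero magnitudes: every bin ties; the first (lowest) frequency wins
        pf = peak_frequency(spec)
        assert pf == spec.freqs[0]
        assert 4.5 <= pf <= 4.5 + FS / 645

    def test_seam_has_no_gap_or_duplicate(self, rng):
        spec = merged_spectrum(rng.normal(size=645), rng.normal(size=645), FS)
        assert np.all(np.diff(spec.freqs) > 0)
        assert spec.freqs[0] >= 4.5 and spec.freqs[-1] <= 400.0
        low_f = spec.freqs[spec.source == "low"]
        high_f = spec.freqs[spec.source == "high"]
        assert low_f.max() <= 160.0 < high_f.min()
        # merged grid == all bins of the common FFT grid within [4.5, 400]
        full = np.fft.rfftfreq(645, d=1 / FS)
        expected = full[(full >= 4.5) & (full <= 400.0)]
        np.testing.assert_allclose(spec.freqs, expected)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            merged_spectrum(np.zeros(100), np.zeros(99), FS)

    def test_against_direct_dft_oracle(self, rng):
        x_low = rng.normal(size=64)
        x_high = rng.normal(size=64)
        freqs = np.fft.rfftfreq(64, d=1 / FS)
        oracle_low = dft_oracle(x_low)
        oracle_high = dft_oracle(x_high)
        spec = merged_spectrum(x_low, x_high, FS)
        for f, m, src in zip(spec.freqs, spec.magnitudes, spec.source):
            i = int(np.argmin(np.abs(freqs - f)))
            expected = oracle_low[i] if src == "low" else oracle_high[i]
            assert m == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_parseval(self, rng):
        v = rng.normal(size=645)
        freqs, mags = spectrum_magnitudes(v, FS)
        # one-sided spectrum: double interior bins (N odd → no Nyquist bin)
        weights = np.full(len(mags), 2.0)
        weights[0] = 1.0
        lhs = float(np.sum(weights * mags**2))
        rhs = 645 * float(np.sum(v**2))
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestFeatureSet:
    def test_extract_features_consistency(self, small_session):
        session, events, _ = small_session
        from seismocrab import extract_feature_window

        w = extract_feature_window(session, events[0])
        f = extract_features(w)
        assert f.sum_norm_energy == pytest.approx(f.energy_low + f.energy_high, rel=1e-12)
        assert f.sum_norm_energy == pytest.approx(summed_energy(w), rel=1e-12)
        assert 4.5 <= f.peak_frequency <= 400.0
        assert f.peak_amp_low >= 0 and f.peak_amp_high >= 0
        assert f.log_energy == pytest.approx(math.log(f.sum_norm_energy))
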