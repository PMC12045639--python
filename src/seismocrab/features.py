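"""Basic seismic signal features of a 0.4 s behaviour window.

Four features characterise each window: the absolute peak amplitude of each
close geophone, the summed normalised energy of the close pair, and the peak
frequency of a merged dual-band spectrum.  Normalised energy is half the sum
of squared velocity samples, E = (Σ v_i²)/2, in (m/s)².  The merged spectrum
splices the low-frequency geophone's FFT (4.5–160 Hz) with the
high-frequency geophone's FFT filtered to >160 Hz, giving one continuous
magnitude spectrum from 4.5 to 400 Hz from which the peak frequency is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import BAND_RANGES
from .windowing import SignalWindow

MERGE_SEAM_HZ = 160.0  # inclusive to the low channel
FLOOR_HZ = 4.5
CEIL_HZ = 400.0


def peak_amplitude(segment: np.ndarray) -> float:
    """Absolute peak amplitude max|v| of a velocity segment (m/s)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.max(np.abs(segment)))


def normalized_energy(segment: np.ndarray) -> float:
    """Normalised energy (Σ v²)/2 of a velocity segment, in (m/s)²."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.sum(segment * segment) / 2.0)


def summed_energy(window: SignalWindow) -> float:
    """Sum of normalised energy over the close geophone pair."""
    for key in ("close_low", "close_high"):
        if key not in window.segments:
            raise ValueError(f"window missing channel {key}")
    return normalized_energy(window.segments["close_low"]) + normalized_energy(
        window.segments["close_high"]
    )


def log_energy(energy: float) -> float:
    """Natural log of an energy value (the scale used for energy boxplots
    and mixed-model responses)."""
    if energy <= 0:
        raise ValueError(f"log energy requires a positive energy, got {energy}")
    return math.log(energy)


@dataclass
class MergedSpectrum:
    """Continuous 4.5–400 Hz magnitude spectrum spliced from the two bands.

    ``source`` records per-bin provenance: bins at or below the 160 Hz seam
    come from the low-frequency geophone, bins above it from the
    high-frequency geophone.
    """

    freqs: np.ndarray
    magnitudes: np.ndarray
    source: np.ndarray  # 'low' / 'high' per bin

    def __post_init__(self) -> None:
        if not (len(self.freqs) == len(self.magnitudes) == len(self.source)):
            raise ValueError("freqs, magnitudes and source must align")
        if len(self.freqs) > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("merged spectrum frequencies must be strictly increasing")


def spectrum_magnitudes(segment: np.ndarray, fs: float, demean: bool = False):
    """One-sided FFT magnitude spectrum of a segment; returns (freqs, |X_k|)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("segment must have at least 2 samples")
    if demean:
        segment = segment - segment.mean()
    mags = np.abs(np.fft.rfft(segment))
    freqs = np.fft.rfftfreq(segment.size, d=1.0 / fs)
    return freqs, mags


def merged_spectrum(
    low_segment: np.ndarray,
    high_segment: np.ndarray,
    fs: float,
    demean: bool = False,
) -> MergedSpectrum:
    """Merge the two geophones' FFTs into one continuous 4.5–400 Hz spectrum.

    Both segments must be equal length so the two transforms share a bin
    grid.  Low-channel bins are retained for 4.5 ≤ f ≤ 160 Hz, high-channel
    bins for 160 < f ≤ 400 Hz; below 4.5 Hz neither sensor responds and the
    bins are discarded.
    """
    low_segment = np.asarray(low_segment, dtype=float)
    high_segment = np.asarray(high_segment, dtype=float)
    if low_segment.shape != high_segment.shape:
        raise ValueError("low and high segments must be equal length")
    freqs, low_mags = spectrum_magnitudes(low_segment, fs, demean=demean)
    _, high_mags = spectrum_magnitudes(high_segment, fs, demean=demean)
    low_mask = (freqs >= FLOOR_HZ) & (freqs <= MERGE_SEAM_HZ)
    high_mask = (freqs > MERGE_SEAM_HZ) & (freqs <= CEIL_HZ)
    merged_freqs = np.concatenate([freqs[low_mask], freqs[high_mask]])
    merged_mags = np.concatenate([low_mags[low_mask], high_mags[high_mask]])
    source = np.concatenate(
        [np.full(low_mask.sum(), "low"), np.full(high_mask.sum(), "high")]
    )
    return MergedSpectrum(freqs=merged_freqs, magnitudes=merged_mags, source=source)


def peak_frequency(spec: MergedSpectrum) -> float:
    """Frequency (Hz) of the maximum magnitude; ties resolve to the lowest
    frequency (argmax takes the first of equal bins on the increasing grid)."""
    if len(spec.freqs) == 0:
        raise ValueError("empty spectrum")
    return float(spec.freqs[int(np.argmax(spec.magnitudes))])


@dataclass
class FeatureSet:
    """The basic features of one behaviour window."""

    peak_amp_low: float  # m/s, close low-frequency geophone
    peak_amp_high: float  # m/s, close high-frequency geophone
    energy_low: float  # (m/s)²
    energy_high: float  # (m/s)²
    sum_norm_energy: float  # (m/s)²
    log_energy: float
    peak_frequency: float  # Hz


def extract_features(window: SignalWindow, demean: bool = False) -> FeatureSet:
    """All basic features of a 0.4 s window from the close geophone pair."""
    low = window.segments["close_low"]
    high = window.segments["close_high"]
    e_low = normalized_energy(low)
    e_high = normalized_energy(high)
    total = e_low + e_high
    spec = merged_spectrum(low, high, window.fs, demean=demean)
    return FeatureSet(
        peak_amp_low=peak_amplitude(low),
        peak_amp_high=peak_amplitude(high),
        energy_low=e_low,
        energy_high=e_high,
        sum_norm_energy=total,
        log_energy=log_energy(total) if total > 0 else float("-inf"),
        peak_frequency=peak_frequency(spec),
    )
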