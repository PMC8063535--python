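"""Distogram → normalized signal → power spectral density.

The distogram is turned into a frequency histogram (counts / total pairs),
smoothed with a 3-wide moving average to mask the universal three-base genomic
periodicity, and normalized for distance decay by subtracting a local average
taken over a ~10-wide window. The PSD of the resulting signal is estimated by
FFT on the frequency grid k/L for k = 1..L/2, so with the default L = 200 the
grid runs 0.005, 0.010, ..., 0.500 cycles/bp (periods 200 down to 2 bp).

PSD scale convention: psd[k] = |DFT(s)[k]|² / L². Fold-changes and empirical
p-values downstream are invariant to any fixed positive rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import Distogram

__all__ = [
    "PeriodicitySpectrum",
    "to_frequency_histogram",
    "moving_average",
    "detrend",
    "normalize_distogram",
    "compute_psd",
    "period_of",
]

#: default moving-average width masking the 3-bp genomic periodicity
SMOOTH_WINDOW = 3
#: default local-average width for distance-decay normalization
DETREND_WINDOW = 10


def to_frequency_histogram(d: Distogram) -> np.ndarray:
    """Distance counts as relative frequencies (vector sums to 1).

    A degenerate distogram (no pairs) maps to the zero vector; callers can
    detect this via ``d.is_degenerate``.
    """
    if d.is_degenerate:
        return np.zeros(d.max_distance, dtype=float)
    return d.counts / d.n_pairs_total


def moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with an odd window; edges shrink symmetrically.

    At position i the mean is taken over the available neighbors within
    (w-1)/2 on each side, so output length equals input length and no padding
    value is invented.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window width must be odd and >= 1, got {w}")
    x = np.asarray(x, dtype=float)
    if w == 1:
        return x.copy()
    kernel = np.ones(w)
    sums = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / norm


def detrend(x: np.ndarray, w: int = DETREND_WINDOW) -> np.ndarray:
    """Subtract the local average, removing the distance-decay trend.

    The local average uses the centered odd window of width >= ``w`` (w=10
    becomes 11: a trailing even window would phase-shift the signal).
    """
    if w < 2:
        raise ValueError(f"detrend window must be >= 2, got {w}")
    w_odd = w if w % 2 == 1 else w + 1
    x = np.asarray(x, dtype=float)
    return x - moving_average(x, w_odd)


def normalize_distogram(
    d: Distogram,
    smooth_window: int = SMOOTH_WINDOW,
    detrend_window: int = DETREND_WINDOW,
) -> np.ndarray:
    """Full normalization: frequency histogram → smooth → detrend."""
    return detrend(moving_average(to_frequency_histogram(d), smooth_window), detrend_window)


@dataclass(frozen=True)
class PeriodicitySpectrum:
    """PSD on the frequency grid k/L, k = 1..floor(L/2); DC term excluded."""

    freqs: np.ndarray
    periods: np.ndarray
    psd: np.ndarray

    @property
    def is_degenerate(self) -> bool:
        return bool(np.all(self.psd == 0.0))

    def psd_at_period(self, period: float) -> tuple[float, float]:
        """(psd, grid frequency) at the grid point nearest to 1/period."""
        i = int(np.argmin(np.abs(self.freqs - 1.0 / period)))
        return float(self.psd[i]), float(self.freqs[i])


def compute_psd(signal: np.ndarray) -> PeriodicitySpectrum:
    """Power spectral density of the normalized signal by FFT.

    psd[k] = |DFT(signal)[k]|² / L² on frequencies k/L for k = 1..floor(L/2).
    """
    signal = np.asarray(signal, dtype=float)
    L = signal.size
    if L < 4:
        raise ValueError(f"signal too short for spectral estimation (L={L} < 4)")
    spectrum = np.fft.rfft(signal)[1 : L // 2 + 1]
    psd = np.abs(spectrum) ** 2 / L**2
    k = np.arange(1, L // 2 + 1)
    freqs = k / L
    return PeriodicitySpectrum(freqs=freqs, periods=1.0 / freqs, psd=psd)


def period_of(freq: float) -> float:
    """Period in bp corresponding to a frequency in cycles/bp (1/freq)."""
    if freq <= 0:
        raise ValueError(f"frequency must be positive, got {freq}")
    return 1.0 / freq


def spectrum_of_distogram(
    d: Distogram,
    smooth_window: int = SMOOTH_WINDOW,
    detrend_window: int = DETREND_WINDOW,
) -> PeriodicitySpectrum:
    """Convenience: distogram straight to its periodicity spectrum."""
    return compute_psd(normalize_distogram(d, smooth_window, detrend_window))
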