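"""Transition-shape and high-state spectral analyses.

The angular-velocity profile quantifies how fast the conductance swings
during a binding (rising) or release (falling) transition: for each
adjacent point pair on a smoothed transition curve,
omega = arctan((y2-y1)/(x2-x1)), and the full width at half maximum of
the |omega| peak summarizes the transition speed.  Smoothing is a simple
moving average — a documented stand-in for the trajectory-clustering
curve fit used in the original workflow.

The high-state power spectrum exposes the low-frequency vibrations that
ride on the degradation-state current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


def angular_velocity(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """omega = arctan(dy/dx) per adjacent pair; vertical pairs give +-pi/2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    dx, dy = np.diff(x), np.diff(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.arctan(dy / dx)
    vertical = dx == 0
    omega[vertical] = np.sign(dy[vertical]) * np.pi / 2
    return omega


def fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation at half-height."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    peak = np.argmax(y)
    half = y[peak] / 2.0
    left = x[0]
    for i in range(peak, 0, -1):
        if y[i - 1] <= half:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + frac * (x[i] - x[i - 1])
            break
    right = x[-1]
    for i in range(peak, x.size - 1):
        if y[i + 1] <= half:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = x[i] + frac * (x[i + 1] - x[i])
            break
    return float(right - left)


@dataclass
class AngularVelocitySeries:
    omegas: np.ndarray
    times: np.ndarray            # midpoint time of each pair
    fwhm: float                  # s, width of the |omega| peak


def angular_velocity_profile(times: np.ndarray, currents: np.ndarray,
                             smooth_window: int = 1) -> AngularVelocitySeries:
    """omega series and |omega|-peak FWHM for one transition segment.

    Apply separately to rising (binding) and falling (release) segments
    to compare their widths.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(currents, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        c = np.convolve(c, kernel, mode="same")
    om = angular_velocity(t, c)
    mid = 0.5 * (t[:-1] + t[1:])
    return AngularVelocitySeries(om, mid, fwhm(mid, np.abs(om)))


@dataclass
class SpectrumPeaks:
    freqs: np.ndarray
    power: np.ndarray
    peak_freqs: np.ndarray
    n_skipped: int


def highstate_spectrum(segments: list[np.ndarray], sampling_rate: float,
                       cutoff: float = 2000.0, min_len: int = 64,
                       threshold: float | None = None,
                       threshold_factor: float = 50.0) -> SpectrumPeaks:
    """Averaged detrended, Hann-windowed power spectrum of high-state visits.

    Segments shorter than ``min_len`` samples are skipped (counted in
    ``n_skipped``).  Peaks are local maxima exceeding ``threshold``
    (absolute power) or ``threshold_factor`` times the median power, and
    only frequencies below the filter ``cutoff`` are reported.
    """
    usable = [np.asarray(s, dtype=float) for s in segments
              if np.size(s) >= min_len]
    n_skipped = len(segments) - len(usable)
    if not usable:
        raise ValueError("no high-state segment reaches the minimum length")
    nfft = int(2 ** np.ceil(np.log2(max(s.size for s in usable))))
    acc = None
    for s in usable:
        d = signal.detrend(s)
        w = signal.get_window("hann", s.size)
        f, p = signal.periodogram(d * w, fs=sampling_rate, nfft=nfft,
                                  window="boxcar")
        acc = p if acc is None else acc + p
    power = acc / len(usable)
    if threshold is None:
        threshold = threshold_factor * float(np.median(power[1:]))
    idx, _ = signal.find_peaks(power, height=threshold)
    peak_freqs = f[idx]
    peak_freqs = peak_freqs[peak_freqs < cutoff]
    return SpectrumPeaks(f, power, peak_freqs, n_skipped)
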