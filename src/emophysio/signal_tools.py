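"""Shared filtering and resampling helpers used by the per-signal extractors."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = ["butter_lowpass", "lowpass_resample", "fir_bandpass", "band_integral"]


def butter_lowpass(x: np.ndarray, rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def lowpass_resample(
    x: np.ndarray, rate: float, target_rate: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Anti-alias with a zero-phase Butterworth low-pass, then resample.

    Handles non-integer rate ratios (e.g. 2048 -> 250 Hz) through rational
    polyphase resampling.
    """
    if target_rate > rate:
        raise ValueError(f"target rate {target_rate} exceeds input rate {rate}")
    y = butter_lowpass(x, rate, cutoff, order=order)
    if target_rate == rate:
        return y
    frac = Fraction(target_rate / rate).limit_denominator(4096)
    # 'line' padding avoids large edge transients on nonzero-baseline signals
    return signal.resample_poly(y, frac.numerator, frac.denominator, axis=-1,
                                padtype="line")


def fir_bandpass(
    x: np.ndarray, rate: float, lo: float, hi: float, transition: float = 1.0
) -> np.ndarray:
    """Zero-phase FIR band-pass via firwin + filtfilt.

    ``transition`` sets the approximate edge width in Hz, which fixes the
    filter length; the result is applied forward-backward for zero phase.
    """
    numtaps = int(3.3 * rate / transition)
    numtaps = min(numtaps, (x.shape[-1] - 1) // 3)  # filtfilt pad constraint
    if numtaps % 2 == 0:
        numtaps -= 1
    if numtaps < 9:
        raise ValueError("input too short for the requested band-pass filter")
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=rate)
    return signal.filtfilt(taps, [1.0], x, axis=-1)


def band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Integrate a PSD over [lo, hi] by the trapezoid rule on the given grid."""
    m = (freqs >= lo) & (freqs <= hi)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))
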