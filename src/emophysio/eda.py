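"""Electrodermal activity: tonic/phasic decomposition, SCR detection, and
the 17-feature registry.

The skin-conductance signal is low-passed at 2 Hz (4th-order zero-phase
Butterworth), resampled to 5 Hz, and split into a tonic component (4 s
centered running median, window shrinking at the edges) and a phasic
component (signal minus tonic). Skin-conductance responses are spans of the
phasic component from an upward crossing of 0.01 uS to the next downward
crossing of 0.0 uS, with the peak at the span maximum.

Three of the seventeen features are defined explicitly by the analysis
(peak rise time; mean first derivative and maximum signed excursion of the
0.5-1 Hz band-passed signal); the rest are a frozen registry of standard
electrodermal statistics (moments, absolute differences of the raw and
z-scored signal, tonic/phasic summaries, SCR counts and amplitudes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .signal_tools import lowpass_resample

__all__ = [
    "SCREvent",
    "GSR_FEATURE_NAMES",
    "decompose_gsr",
    "detect_scr",
    "gsr_feature_vector",
]

WORK_RATE = 5.0        # Hz after the filter/decimate chain
MEDIAN_WIN_S = 4.0
ONSET_THRESHOLD = 0.01  # uS
OFFSET_THRESHOLD = 0.0  # uS
DERIV_BAND = (0.5, 1.0)

GSR_FEATURE_NAMES = (
    "gsr_mean",
    "gsr_sd",
    "gsr_mean_abs_diff",
    "gsr_mean_abs_diff_z",
    "gsr_mean_abs_diff2",
    "gsr_mean_abs_diff2_z",
    "gsr_tonic_mean",
    "gsr_tonic_slope",
    "gsr_phasic_mean",
    "gsr_phasic_sd",
    "gsr_scr_count",
    "gsr_scr_rate_per_min",
    "gsr_scr_amp_mean",
    "gsr_scr_amp_sum",
    "gsr_peaks_rise_time",
    "gsr_derivative",
    "gsr_max_signed_amplitude",
)


@dataclass(frozen=True)
class SCREvent:
    """One skin-conductance response on the phasic component."""

    onset_time: float
    peak_time: float
    offset_time: float
    amplitude: float  # uS, phasic value at the peak

    @property
    def rise_time(self) -> float:
        return self.peak_time - self.onset_time


def preprocess_gsr(gsr: np.ndarray, rate: float) -> np.ndarray:
    """2 Hz low-pass then resample to the 5 Hz working rate."""
    return lowpass_resample(np.asarray(gsr, dtype=float), rate, WORK_RATE, cutoff=2.0)


def decompose_gsr(gsr: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Split into (tonic, phasic) at 5 Hz.

    ``gsr`` may be the raw signal at any rate >= 5 Hz; the stated
    filter/decimate chain is applied first. Tonic is the 4 s centered running
    median; phasic is the residual.
    """
    x = preprocess_gsr(gsr, rate) if rate != WORK_RATE else np.asarray(gsr, float)
    win = int(round(MEDIAN_WIN_S * WORK_RATE))
    if win % 2 == 0:
        win += 1
    if len(x) < win:
        raise ValueError("segment shorter than the median window")
    tonic = (
        pd.Series(x).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    return tonic, x - tonic


def detect_scr(phasic: np.ndarray, rate: float = WORK_RATE) -> list[SCREvent]:
    """Detect SCR events on the phasic component.

    Onset at the upward crossing of 0.01 uS, offset at the next downward
    crossing of 0.0 uS (or the segment end), peak at the span maximum. Spans
    that never fall back below the offset threshold merge into one event.
    """
    phasic = np.asarray(phasic, dtype=float)
    events: list[SCREvent] = []
    n = len(phasic)
    i = 0
    while i < n - 1:
        if phasic[i] <= ONSET_THRESHOLD < phasic[i + 1]:
            onset = i + 1
            j = onset
            while j < n - 1 and phasic[j + 1] >= OFFSET_THRESHOLD:
                j += 1
            offset = min(j + 1, n - 1)
            if offset - onset >= 2:
                peak = onset + 1 + int(np.argmax(phasic[onset + 1: offset]))
                events.append(
                    SCREvent(onset / rate, peak / rate, offset / rate,
                             float(phasic[peak]))
                )
            i = offset + 1
        else:
            i += 1
    return events


def _bandpassed(x: np.ndarray, rate: float) -> np.ndarray:
    sos = signal.butter(4, DERIV_BAND, btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def _max_signed_excursion(bp: np.ndarray) -> float:
    """Maximum |difference| (kept signed) between consecutive extrema of the
    band-passed signal."""
    peaks, _ = signal.find_peaks(bp)
    troughs, _ = signal.find_peaks(-bp)
    idx = np.sort(np.concatenate([peaks, troughs]))
    if len(idx) < 2:
        return 0.0
    diffs = np.diff(bp[idx])
    return float(diffs[np.argmax(np.abs(diffs))])


def gsr_feature_vector(
    gsr: np.ndarray, rate: float
) -> tuple[dict[str, float], list[str]]:
    """The 17-feature electrodermal registry for one window.

    Returns (features, flags); with zero detected SCRs the peak-dependent
    features are 0 and a flag is raised.
    """
    x = preprocess_gsr(gsr, rate)
    tonic, phasic = decompose_gsr(x, WORK_RATE)
    events = detect_scr(phasic, WORK_RATE)
    duration_min = len(x) / WORK_RATE / 60.0
    flags: list[str] = []

    z = (x - x.mean()) / x.std() if x.std() > 0 else np.zeros_like(x)
    d1, d1z = np.diff(x), np.diff(z)
    d2, d2z = np.diff(x, n=2), np.diff(z, n=2)
    t = np.arange(len(x)) / WORK_RATE
    slope = float(np.polyfit(t, tonic, 1)[0]) if len(x) > 1 else 0.0
    bp = _bandpassed(x, WORK_RATE)

    if events:
        amps = np.array([e.amplitude for e in events])
        rise = float(np.mean([e.rise_time for e in events]))
        amp_mean, amp_sum = float(amps.mean()), float(amps.sum())
    else:
        flags.append("no_scr_detected")
        rise = amp_mean = amp_sum = 0.0

    feats = {
        "gsr_mean": float(x.mean()),
        "gsr_sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        "gsr_mean_abs_diff": float(np.mean(np.abs(d1))),
        "gsr_mean_abs_diff_z": float(np.mean(np.abs(d1z))),
        "gsr_mean_abs_diff2": float(np.mean(np.abs(d2))),
        "gsr_mean_abs_diff2_z": float(np.mean(np.abs(d2z))),
        "gsr_tonic_mean": float(tonic.mean()),
        "gsr_tonic_slope": slope,
        "gsr_phasic_mean": float(phasic.mean()),
        "gsr_phasic_sd": float(phasic.std(ddof=1)) if len(phasic) > 1 else 0.0,
        "gsr_scr_count": float(len(events)),
        "gsr_scr_rate_per_min": float(len(events)) / duration_min,
        "gsr_scr_amp_mean": amp_mean,
        "gsr_scr_amp_sum": amp_sum,
        "gsr_peaks_rise_time": rise,
        "gsr_derivative": float(np.mean(np.diff(bp) * WORK_RATE)),
        "gsr_max_signed_amplitude": _max_signed_excursion(bp),
    }
    assert tuple(feats) == GSR_FEATURE_NAMES
    return feats, flags
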