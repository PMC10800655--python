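"""Pupillometry: binocular cleaning and the 9-feature spectral registry.

Cleaning applies, in order: the physiological range rule (diameters outside
2-8 mm are invalid, marking blinks), the jump rule (changes above 0.375 mm
within 20 ms are acquisition artifacts; both endpoints are invalidated),
one-eye substitution where only one eye is invalid, cubic-spline
interpolation where both are, then a 4th-order zero-phase 5 Hz Butterworth
low-pass and decimation to 10 Hz. Spectra use Welch's periodogram on the
linearly detrended 10 Hz trace with 1.875 s Hamming segments at 50% overlap;
the high-frequency band is 0.15-0.45 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .signal_tools import band_integral, lowpass_resample

__all__ = [
    "PupilTrace",
    "CleanPupil",
    "PUPIL_FEATURE_NAMES",
    "clean_pupil",
    "pupil_psd",
    "pupil_feature_vector",
]

RANGE_MM = (2.0, 8.0)
JUMP_MM = 0.375
JUMP_SPAN_S = 0.020
WORK_RATE = 10.0
WELCH_SEG_S = 1.875
NFFT = 256  # zero-padded grid so sub-Hz bands are resolvable

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.45)

PUPIL_FEATURE_NAMES = (
    "pupil_mean",
    "pupil_sd",
    "pupil_vlf",
    "pupil_lf",
    "pupil_hf",
    "pupil_lfn",
    "pupil_hfn",
    "pupil_lf_hf",
    "pupil_tot",
)


@dataclass
class PupilTrace:
    """Binocular diameter samples (mm) at a common rate (60 Hz nominal)."""

    left: np.ndarray
    right: np.ndarray
    rate: float = 60.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right traces must have equal length")


@dataclass
class CleanPupil:
    """Cleaning result: fused trace at the input rate, the per-sample validity
    masks, and the low-passed 10 Hz series the spectra are computed on."""

    fused: np.ndarray          # at input rate, after substitution/interpolation
    valid_left: np.ndarray
    valid_right: np.ndarray
    clean: np.ndarray          # at WORK_RATE
    rate: float = WORK_RATE
    flags: list = field(default_factory=list)


def _invalid_mask(x: np.ndarray, rate: float) -> np.ndarray:
    bad = (x < RANGE_MM[0]) | (x > RANGE_MM[1]) | ~np.isfinite(x)
    # jump rule: |difference| over any span <= 20 ms marks both endpoints
    max_k = max(1, int(np.floor(JUMP_SPAN_S * rate)))
    for k in range(1, max_k + 1):
        jump = np.abs(x[k:] - x[:-k]) > JUMP_MM
        idx = np.flatnonzero(jump)
        bad[idx] = True
        bad[idx + k] = True
    return bad


def clean_pupil(trace: PupilTrace, max_gap_s: float = 2.0) -> CleanPupil:
    """Apply the range/jump/blink rules, fuse the two eyes, filter to 10 Hz."""
    bad_l = _invalid_mask(trace.left, trace.rate)
    bad_r = _invalid_mask(trace.right, trace.rate)
    fused = 0.5 * (trace.left + trace.right)
    only_l = bad_l & ~bad_r
    only_r = bad_r & ~bad_l
    fused[only_l] = trace.right[only_l]
    fused[only_r] = trace.left[only_r]
    both = bad_l & bad_r
    flags: list[str] = []
    if both.any():
        good = np.flatnonzero(~both)
        if len(good) < 4:
            raise ValueError("not enough valid samples to interpolate")
        t = np.arange(len(fused))
        cs = interpolate.CubicSpline(t[good], fused[good])
        fused[both] = cs(t[both])
        # flag gaps longer than the configured maximum
        edges = np.flatnonzero(np.diff(np.concatenate([[0], both.view(np.int8), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            if (b - a) / trace.rate > max_gap_s:
                flags.append(f"gap_over_{max_gap_s}s_at_{a / trace.rate:.2f}s")
    clean = lowpass_resample(fused, trace.rate, WORK_RATE, cutoff=5.0)
    return CleanPupil(fused, ~bad_l, ~bad_r, clean, WORK_RATE, flags)


def pupil_psd(clean: np.ndarray, rate: float = WORK_RATE
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram of the linearly detrended trace (1.875 s Hamming
    segments, 50% overlap, zero-padded frequency grid)."""
    clean = np.asarray(clean, dtype=float)
    nperseg = int(WELCH_SEG_S * rate)
    if len(clean) < 2 * nperseg:
        raise ValueError("trace shorter than two Welch segments")
    return signal.welch(
        signal.detrend(clean), fs=rate, window="hamming", nperseg=nperseg,
        noverlap=nperseg // 2, nfft=NFFT, detrend=False,
    )


def pupil_feature_vector(
    trace: PupilTrace, max_gap_s: float = 2.0
) -> tuple[dict[str, float], list[str]]:
    """The 9-feature pupillometry registry for one window."""
    res = clean_pupil(trace, max_gap_s=max_gap_s)
    x = res.clean
    freqs, psd = pupil_psd(x)
    vlf = band_integral(freqs, psd, *VLF_BAND)
    lf = band_integral(freqs, psd, *LF_BAND)
    hf = band_integral(freqs, psd, *HF_BAND)
    tot = band_integral(freqs, psd, 0.0, HF_BAND[1])
    denom = lf + hf
    feats = {
        "pupil_mean": float(x.mean()),
        "pupil_sd": float(x.std(ddof=1)),
        "pupil_vlf": vlf,
        "pupil_lf": lf,
        "pupil_hf": hf,
        "pupil_lfn": lf / denom if denom > 0 else np.nan,
        "pupil_hfn": hf / denom if denom > 0 else np.nan,
        "pupil_lf_hf": lf / hf if hf > 0 else np.nan,
        "pupil_tot": tot,
    }
    assert tuple(feats) == PUPIL_FEATURE_NAMES
    return feats, res.flags
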