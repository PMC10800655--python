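"""EEG band-power features: regional spectral powers, attention, engagement.

The 21-channel recording is band-passed 1-45 Hz with a zero-phase FIR filter
and common-average referenced. Per region (frontal, parietal), Welch band
powers in the delta (1-3 Hz), theta (4-7 Hz), alpha (8-12 Hz) and beta
(16-38 Hz) bands are normalized by the total 1-45 Hz power; the beta/theta
ratio (attention index) and beta/alpha ratio (engagement index) are computed
from the raw band integrals, where the normalizer cancels.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .signal_tools import band_integral, fir_bandpass

__all__ = [
    "EEG_BANDS",
    "TOTAL_BAND",
    "REGIONS",
    "EEG_FEATURE_NAMES",
    "preprocess_eeg",
    "band_power_normalized",
    "eeg_feature_vector",
]

EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (16.0, 38.0),
}
TOTAL_BAND = (1.0, 45.0)

# 10-20 nomenclature prefixes: F*/Fp* frontal, P*/Pz parietal (configurable)
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8"),
    "parietal": ("Pz", "P3", "P4", "P7", "P8"),
}

EEG_FEATURE_NAMES = tuple(
    f"eeg_{region}_{name}"
    for region in ("frontal", "parietal")
    for name in ("delta", "theta", "alpha", "beta", "beta_theta", "beta_alpha")
)

WELCH_SEG_S = 2.0  # Hamming segments, 50% overlap


def preprocess_eeg(raw: np.ndarray, rate: float) -> np.ndarray:
    """Zero-phase FIR band-pass 1-45 Hz, then common-average referencing."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if rate <= 90.0:
        raise ValueError("sampling rate too low for 1-45 Hz content")
    if raw.shape[0] < 2:
        raise ValueError("common-average referencing needs at least 2 channels")
    x = fir_bandpass(raw, rate, *TOTAL_BAND, transition=1.0)
    return x - x.mean(axis=0, keepdims=True)


def _group_psd(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD averaged over channels (mean of per-channel PSDs)."""
    x = np.atleast_2d(x)
    nperseg = min(int(WELCH_SEG_S * rate), x.shape[-1])
    freqs, psd = signal.welch(x, fs=rate, window="hamming", nperseg=nperseg,
                              noverlap=nperseg // 2, axis=-1)
    return freqs, psd.mean(axis=0)


def band_power_normalized(channel_group: np.ndarray, rate: float,
                          band: tuple[float, float]) -> float:
    """Band power as a fraction of total 1-45 Hz power, in [0, 1]."""
    channel_group = np.atleast_2d(channel_group)
    if channel_group.shape[0] == 0:
        raise ValueError("empty channel group")
    if channel_group.shape[-1] < 2 * int(WELCH_SEG_S * rate) // 1:
        # need at least two Welch segments for a stable estimate
        if channel_group.shape[-1] < int(WELCH_SEG_S * rate):
            raise ValueError("segment shorter than one Welch window")
    freqs, psd = _group_psd(channel_group, rate)
    total = band_integral(freqs, psd, *TOTAL_BAND)
    if total <= 0:
        return 0.0
    return band_integral(freqs, psd, *band) / total


def eeg_feature_vector(
    eeg: np.ndarray,
    rate: float,
    channel_names: tuple[str, ...],
    regions: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, float]:
    """The 12 EEG features of one window: per region, the four normalized
    band powers plus the attention (beta/theta) and engagement (beta/alpha)
    ratios computed from raw band integrals."""
    regions = regions or REGIONS
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    if eeg.shape[0] != len(channel_names):
        raise ValueError("channel_names must match the EEG row count")
    clean = preprocess_eeg(eeg, rate)
    index = {ch: i for i, ch in enumerate(channel_names)}
    out: dict[str, float] = {}
    for region in ("frontal", "parietal"):
        rows = [index[ch] for ch in regions[region] if ch in index]
        if not rows:
            raise ValueError(f"no channels found for region {region}")
        group = clean[rows]
        freqs, psd = _group_psd(group, rate)
        total = band_integral(freqs, psd, *TOTAL_BAND)
        raw = {b: band_integral(freqs, psd, *EEG_BANDS[b]) for b in EEG_BANDS}
        for b in EEG_BANDS:
            out[f"eeg_{region}_{b}"] = raw[b] / total if total > 0 else 0.0
        out[f"eeg_{region}_beta_theta"] = (
            raw["beta"] / raw["theta"] if raw["theta"] > 0 else np.nan)
        out[f"eeg_{region}_beta_alpha"] = (
            raw["beta"] / raw["alpha"] if raw["alpha"] > 0 else np.nan)
    return out
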