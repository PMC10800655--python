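"""Respiration features and cardio-respiratory coupling (8-feature registry).

The respiration belt signal is low-passed at 1 Hz with a zero-phase
Parks-McClellan (equiripple FIR) filter; breath cycles are alternating
minimum/maximum pairs found by thresholded peak picking. Coupling between
the RR series and respiration resampled at beat times is summarized by a
bivariate autoregression: directional transfer gains (respiration-to-RR, the
respiratory-sinus-arrhythmia gain, and the reverse feedforward gain) are
band-averaged over the high-frequency band, while coherence and cross-spectral
magnitude are band-integrated over the LF and HF bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cardio import BeatSeries, HF_BAND, LF_BAND
from .signal_tools import band_integral

__all__ = [
    "RespFeatures",
    "RESP_FEATURE_NAMES",
    "resp_lowpass",
    "resp_extrema",
    "bivariate_coupling",
    "resp_feature_vector",
]

RESP_FEATURE_NAMES = (
    "resp_freq",
    "resp_amp",
    "resp_rsa_gain",
    "resp_ff_gain",
    "resp_coh_lf",
    "resp_coh_hf",
    "resp_crosspow_lf",
    "resp_crosspow_hf",
)

VAR_ORDER = 6  # bivariate AR order


def resp_lowpass(resp: np.ndarray, rate: float, cutoff: float = 1.0) -> np.ndarray:
    """Zero-phase equiripple low-pass (Parks-McClellan design) at 1 Hz."""
    resp = np.asarray(resp, dtype=float)
    if rate < 4.0:
        raise ValueError("respiration rate must be >= 4 Hz")
    trans = min(0.5, (rate / 2 - cutoff) / 2)
    numtaps = min(int(3.3 * rate / trans), (len(resp) - 1) // 3)
    if numtaps % 2 == 0:
        numtaps -= 1
    taps = signal.remez(numtaps, [0, cutoff, cutoff + trans, rate / 2], [1, 0], fs=rate)
    return signal.filtfilt(taps, [1.0], resp)


def resp_extrema(resp: np.ndarray, rate: float) -> list[tuple[float, float, float]]:
    """Breath cycles as (t_min, t_max, amplitude) from the 1 Hz low-passed
    signal. One cycle per detected maximum; the amplitude is max minus the
    preceding minimum (or the following one for an edge-truncated first
    cycle). Near-constant input yields no breaths."""
    x = resp_lowpass(resp, rate)
    span = np.ptp(x)
    if span < 1e-9:
        return []
    prom = 0.2 * span
    peaks, _ = signal.find_peaks(x, prominence=prom)
    troughs, _ = signal.find_peaks(-x, prominence=prom)
    breaths = []
    for p in peaks:
        prev = troughs[troughs < p]
        nxt = troughs[troughs > p]
        if len(prev):
            t = prev[-1]
        elif len(nxt):
            t = nxt[0]
        else:
            continue
        breaths.append((t / rate, p / rate, float(x[p] - x[t])))
    return breaths


@dataclass
class RespFeatures:
    """The eight respiration / cardio-respiratory coupling summaries."""

    freq: float            # Hz, breaths per second
    amp: float             # mean breath amplitude, signal units
    rsa_gain: float        # |H resp->RR| averaged over HF
    ff_gain: float         # |H RR->resp| averaged over HF
    coh_lf: float
    coh_hf: float
    crosspow_lf: float
    crosspow_hf: float
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        vals = (self.freq, self.amp, self.rsa_gain, self.ff_gain,
                self.coh_lf, self.coh_hf, self.crosspow_lf, self.crosspow_hf)
        return dict(zip(RESP_FEATURE_NAMES, vals))


def _var_fit(y: np.ndarray, order: int, ridge: float = 1e-8
             ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares bivariate AR fit. y is (n, 2), demeaned by the caller.
    Returns (coefs with shape (order, 2, 2), residual covariance)."""
    n = len(y)
    rows = n - order
    X = np.hstack([y[order - k - 1: order - k - 1 + rows] for k in range(order)])
    Y = y[order:]
    XtX = X.T @ X + ridge * np.eye(X.shape[1])
    B = np.linalg.solve(XtX, X.T @ Y)  # (2*order, 2)
    resid = Y - X @ B
    sigma = resid.T @ resid / max(rows - 2 * order, 1)
    coefs = B.reshape(order, 2, 2).transpose(0, 2, 1)  # A_k maps y[t-k-1]->y[t]
    return coefs, sigma


def _row_gain(coefs: np.ndarray, f_beat: np.ndarray, target: int) -> np.ndarray:
    """|B(f)| / |A(f)| for the equation of series ``target``: the transfer
    magnitude from the other series' lags to the target, normalized by the
    target's own-lag polynomial. For a beat series driven additively by the
    other channel this recovers the coupling gain at the driving frequency."""
    other = 1 - target
    order = coefs.shape[0]
    phase = np.exp(-2j * np.pi * np.outer(f_beat, np.arange(1, order + 1)))
    a = 1.0 - phase @ coefs[:, target, target]
    b = phase @ coefs[:, target, other]
    return np.abs(b) / np.maximum(np.abs(a), 1e-12)


def bivariate_coupling(
    beats: BeatSeries,
    resp: np.ndarray,
    rate: float,
    window=None,
) -> tuple[dict[str, float], list[str]]:
    """Gains, coherence and cross-spectral power between RR and respiration.

    Respiration is sampled at beat times; a bivariate AR of order 6 is fitted
    by least squares to the demeaned (RR, RESP) beat series. Gains are the
    transfer-function magnitudes averaged over the HF band; coherence is the
    Welch magnitude-squared coherence of the beat series, and cross-power the
    cross-spectral magnitude, both band-integrated over LF and HF.
    """
    if window is not None:
        beats = beats.in_window(window.t_start, window.t_end)
    if len(beats) < 20:
        return ({k: np.nan for k in RESP_FEATURE_NAMES[2:]}, ["too_few_beats"])
    t0 = beats.r_times[0]
    rr = beats.rr
    t_beat = beats.r_times[1:]  # time of each interval's end
    t_resp = np.arange(len(resp)) / rate + (window.t_start if window else t0)
    resp_b = np.interp(t_beat, t_resp, resp)
    dt = float(np.mean(rr))

    y = np.column_stack([rr - rr.mean(), resp_b - resp_b.mean()])
    flags: list[str] = []
    f_hz = np.linspace(1e-3, HF_BAND[1], 256)
    try:
        coefs, _ = _var_fit(y, min(VAR_ORDER, len(y) // 4))
        # evaluate gains where respiration actually drives: the spectral peak
        # of the beat-sampled respiration within the HF band
        f_w, p_w = signal.welch(y[:, 1], fs=1.0 / dt, nperseg=min(32, len(y)))
        hf_w = (f_w >= HF_BAND[0]) & (f_w <= HF_BAND[1])
        if hf_w.any() and p_w[hf_w].max() > 0:
            f_star = float(f_w[hf_w][np.argmax(p_w[hf_w])])
        else:
            f_star = 0.5 * (HF_BAND[0] + HF_BAND[1])
        f_eval = np.array([f_star])
        rsa_gain = float(_row_gain(coefs, f_eval * dt, target=0)[0])
        ff_gain = float(_row_gain(coefs, f_eval * dt, target=1)[0])
    except np.linalg.LinAlgError:
        flags.append("singular_var_fit")
        rsa_gain = ff_gain = np.nan

    fs_beat = 1.0 / dt
    nper = min(32, len(y))
    f_c, coh = signal.coherence(y[:, 1], y[:, 0], fs=fs_beat, nperseg=nper)
    f_x, sxy = signal.csd(y[:, 1], y[:, 0], fs=fs_beat, nperseg=nper)
    coh = np.clip(coh, 0.0, 1.0)

    def band_mean(f, v, band):
        m = (f >= band[0]) & (f <= band[1])
        return float(np.mean(v[m])) if m.any() else np.nan

    out = {
        "resp_rsa_gain": rsa_gain,
        "resp_ff_gain": ff_gain,
        "resp_coh_lf": band_mean(f_c, coh, LF_BAND),
        "resp_coh_hf": band_mean(f_c, coh, HF_BAND),
        "resp_crosspow_lf": band_integral(f_x, np.abs(sxy), *LF_BAND),
        "resp_crosspow_hf": band_integral(f_x, np.abs(sxy), *HF_BAND),
    }
    return out, flags


def resp_feature_vector(
    resp: np.ndarray,
    rate: float,
    beats: BeatSeries,
    window=None,
) -> tuple[dict[str, float], list[str]]:
    """The 8-feature respiration registry for one window."""
    duration = len(resp) / rate
    breaths = resp_extrema(resp, rate)
    flags: list[str] = []
    if len(breaths) < 2:
        flags.append("too_few_breaths")
        freq, amp = np.nan, np.nan
    else:
        freq = len(breaths) / duration
        amp = float(np.mean([b[2] for b in breaths]))
    coupling, cflags = bivariate_coupling(beats, resp, rate, window)
    feats = {"resp_freq": freq, "resp_amp": amp, **coupling}
    assert tuple(feats) == RESP_FEATURE_NAMES
    return feats, flags + cflags
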