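"""ECG and blood-volume-pulse features.

R peaks are detected with the Pan-Tompkins cascade (band-pass, derivative,
squaring, moving-window integration, adaptive thresholding with search-back)
after anti-alias filtering and resampling to 250 Hz. Heart-rate variability
over the short 45 s analysis windows is estimated with a point-process model:
inter-beat intervals follow an inverse-Gaussian density whose mean is a linear
autoregression on the previous intervals, fitted by exponentially weighted
maximum likelihood. Spectral indices come from the fitted AR transfer
function, with the frequency axis mapped to Hz through the mean beat rate.

BVP fiducials (systolic, diastolic, onset) are located per RR interval and
reduced to the mean pulse amplitude (VP) and the mean pulse arrival time (PAT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .signal_tools import band_integral, lowpass_resample

__all__ = [
    "BeatSeries",
    "HRVFeatures",
    "BVPFeatures",
    "detect_r_peaks",
    "fit_ig_pointprocess",
    "bvp_fiducials",
    "bvp_features",
    "ig_rescaled_ks",
    "HRV_FIELDS",
]

WORK_RATE = 250.0  # Hz, internal rate for ECG / BVP processing

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.5)

HRV_FIELDS = ("mu_rr", "sigma2", "vlf", "lf", "hf", "tot", "lf_hf", "lfn", "hfn")


@dataclass
class BeatSeries:
    """Strictly increasing R-peak times (s) and the derived RR intervals."""

    r_times: np.ndarray

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if len(self.r_times) > 1 and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")

    @property
    def rr(self) -> np.ndarray:
        return np.diff(self.r_times)

    def __len__(self) -> int:
        return len(self.r_times)

    def in_window(self, t_start: float, t_end: float) -> "BeatSeries":
        m = (self.r_times >= t_start) & (self.r_times < t_end)
        return BeatSeries(self.r_times[m])

    def to_csv(self, path) -> None:
        import pandas as pd

        rr = np.concatenate([[np.nan], self.rr]) if len(self) else np.array([])
        pd.DataFrame({"time_s": self.r_times, "rr_s": rr}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# R-peak detection


def detect_r_peaks(ecg: np.ndarray, rate: float) -> BeatSeries:
    """Pan-Tompkins QRS detection.

    The raw ECG is low-passed (4th-order zero-phase Butterworth, 100 Hz) and
    resampled to 250 Hz, then passed through the Pan-Tompkins stages. Detected
    peak positions are refined to the local ECG maximum, so timing is accurate
    to about one 250 Hz sample. Thresholds are adaptive and scale-free.
    """
    ecg = np.asarray(ecg, dtype=float)
    if rate < WORK_RATE:
        raise ValueError(f"ECG rate must be >= {WORK_RATE} Hz")
    x = lowpass_resample(ecg, rate, WORK_RATE, cutoff=100.0)
    fs = WORK_RATE
    if np.ptp(x) < 1e-12:
        warnings.warn("flat ECG signal: no beats detected", stacklevel=2)
        return BeatSeries(np.array([]))

    # band-pass 5-15 Hz
    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    # derivative, squaring, moving-window integration (150 ms)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    win = int(round(0.15 * fs))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        warnings.warn("no candidate peaks found", stacklevel=2)
        return BeatSeries(np.array([]))

    # adaptive thresholds (Pan-Tompkins running estimates)
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    qrs: list[int] = []
    rr_avg = None
    for p in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[p] > thr1:
            qrs.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(qrs) > 1:
                rr = qrs[-1] - qrs[-2]
                rr_avg = rr if rr_avg is None else 0.125 * rr + 0.875 * rr_avg
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            # search-back: accept a missed peak above the lower threshold
            if qrs and rr_avg and (p - qrs[-1]) > 1.66 * rr_avg and mwi[p] > 0.5 * thr1:
                qrs.append(p)
                spki = 0.25 * mwi[p] + 0.75 * spki

    # refine each detection to the local R maximum on the resampled ECG
    half = int(round(0.1 * fs))
    r_idx = []
    for p in qrs:
        j0, j1 = max(p - half, 0), min(p + half + 1, len(x))
        r_idx.append(j0 + int(np.argmax(x[j0:j1])))
    r_idx = np.unique(r_idx)
    return BeatSeries(r_idx / fs)


# ---------------------------------------------------------------------------
# inverse-Gaussian point-process HRV


@dataclass
class HRVFeatures:
    """The nine point-process HRV summaries of one 45 s window."""

    mu_rr: float
    sigma2: float
    vlf: float
    lf: float
    hf: float
    tot: float
    lf_hf: float
    lfn: float
    hfn: float
    converged: bool = True
    flags: list = field(default_factory=list)
    # fitted internals kept for goodness-of-fit diagnostics
    mus: np.ndarray | None = None
    lam: float | None = None
    theta: np.ndarray | None = None

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in HRV_FIELDS}


def _ig_negloglik(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                  w: np.ndarray) -> float:
    theta, loglam = params[:-1], params[-1]
    lam = np.exp(loglam)
    mu = X @ theta
    # quadratic penalty keeps the optimizer on the feasible (mu > 0) side
    pen = float(np.sum(np.maximum(1e-3 - mu, 0.0) ** 2)) * 1e8
    mu = np.maximum(mu, 1e-3)
    ll = 0.5 * np.log(lam) - 1.5 * np.log(y) - lam * (y - mu) ** 2 / (2 * mu**2 * y)
    return float(-np.sum(w * ll)) + pen


def fit_ig_pointprocess(
    beats: BeatSeries,
    order: int = 8,
    window=None,
    *,
    forgetting: float = 0.98,
    n_freq: int = 512,
) -> HRVFeatures:
    """Fit the inverse-Gaussian point-process HRV model over one window.

    The IG mean of interval ``i`` is a linear autoregression of order ``p`` on
    the previous intervals; the likelihood is weighted by an exponential
    forgetting factor so recent beats dominate. ``mu_rr`` is the time-averaged
    fitted mean, ``sigma2`` the IG variance ``mu^3/lambda`` averaged over the
    window. Band powers integrate the AR transfer-function spectrum
    ``sigma2 * dt / |A(f)|^2`` with ``f`` mapped to Hz via the mean beat rate.
    """
    if window is not None:
        beats = beats.in_window(window.t_start, window.t_end)
    rr = beats.rr
    if len(rr) < order + 5:
        raise ValueError(f"need at least {order + 5} beats, got {len(rr) + 1}")

    y = rr[order:]
    n = len(y)
    X = np.ones((n, order + 1))
    for j in range(1, order + 1):
        X[:, j] = rr[order - j: order - j + n]
    w = forgetting ** np.arange(n - 1, -1, -1.0)
    w = w * n / w.sum()

    mu0 = float(np.average(y, weights=w))
    var0 = float(np.average((y - mu0) ** 2, weights=w)) + 1e-10
    theta0 = np.zeros(order + 1)
    theta0[0] = mu0
    lam0 = mu0**3 / var0
    x0 = np.concatenate([theta0, [np.log(lam0)]])

    res = optimize.minimize(_ig_negloglik, x0, args=(X, y, w), method="L-BFGS-B",
                            options={"maxiter": 500})
    flags: list[str] = []
    converged = bool(res.success)
    if not converged:
        flags.append(f"ig_fit_not_converged:{res.message}")
    theta = res.x[:-1]
    lam = float(np.exp(res.x[-1]))
    mus = np.maximum(X @ theta, 1e-4)

    mu_rr = float(np.mean(mus))
    sigma2 = float(np.mean(mus**3) / lam)

    # AR spectrum on the beat axis, mapped to Hz by the mean interval
    f_hz = np.linspace(1e-3, HF_BAND[1], n_freq)
    f_beat = f_hz * mu_rr  # cycles per beat
    j = np.arange(1, order + 1)
    A = 1.0 - (theta[1:][None, :] * np.exp(-2j * np.pi * np.outer(f_beat, j) * 1.0)
               ).sum(axis=1) if order > 0 else np.ones_like(f_beat, dtype=complex)
    psd = sigma2 * mu_rr / np.abs(A) ** 2

    vlf = band_integral(f_hz, psd, *VLF_BAND)
    lf = band_integral(f_hz, psd, *LF_BAND)
    hf = band_integral(f_hz, psd, *HF_BAND)
    tot = band_integral(f_hz, psd, 0.0, HF_BAND[1])
    denom = lf + hf
    lfn = lf / denom if denom > 0 else np.nan
    hfn = hf / denom if denom > 0 else np.nan
    lf_hf = lf / hf if hf > 0 else np.nan
    return HRVFeatures(mu_rr, sigma2, vlf, lf, hf, tot, lf_hf, lfn, hfn,
                       converged=converged, flags=flags, mus=mus, lam=lam,
                       theta=theta)


def ig_rescaled_ks(beats: BeatSeries, fit: HRVFeatures, order: int = 8) -> float:
    """Time-rescaling goodness of fit: p-value of a KS test on the
    IG-CDF-transformed intervals (uniform under a correct model)."""
    rr = beats.rr[order:]
    mus = fit.mus
    z = stats.invgauss.cdf(rr, mus / fit.lam, scale=fit.lam)
    return float(stats.kstest(z, "uniform").pvalue)


# ---------------------------------------------------------------------------
# BVP fiducials


def bvp_fiducials(
    bvp: np.ndarray, rate: float, beats: BeatSeries
) -> tuple[list[tuple], int]:
    """Per-RR-interval (systolic, diastolic, onset) fiducials.

    The BVP is low-passed at 25 Hz (4th-order zero-phase Butterworth) and
    resampled to 250 Hz. Within each RR interval the maximum is systolic, the
    minimum diastolic, and the onset is the steepest-ascent point between the
    diastolic minimum and the systolic maximum. Intervals without a rising
    segment are skipped; the skip count is returned.

    Returns (triplets, n_skipped) where each triplet is
    ((t_sys, v_sys), (t_dia, v_dia), (t_onset, v_onset)) in seconds from the
    start of ``bvp``.
    """
    x = lowpass_resample(np.asarray(bvp, dtype=float), rate, WORK_RATE, cutoff=25.0)
    fs = WORK_RATE
    dx = np.gradient(x) * fs
    out = []
    skipped = 0
    times = beats.r_times
    edge_guard = 0.25  # s, zero-phase filter edge transients are unusable
    duration = len(x) / fs
    for t0, t1 in zip(times[:-1], times[1:]):
        if t0 < edge_guard or t1 > duration - edge_guard:
            skipped += 1
            continue
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), len(x))
        if i1 - i0 < 4:
            skipped += 1
            continue
        seg = x[i0:i1]
        i_sys = i0 + int(np.argmax(seg))
        i_dia = i0 + int(np.argmin(seg))
        # degenerate interval: excursion at the filter-ripple level
        if i_dia >= i_sys or np.ptp(seg) < 1e-4 * max(np.abs(seg).mean(), 1e-30):
            skipped += 1
            continue
        i_on = i_dia + int(np.argmax(dx[i_dia:i_sys + 1]))
        out.append(((i_sys / fs, x[i_sys]), (i_dia / fs, x[i_dia]), (i_on / fs, x[i_on])))
    return out, skipped


@dataclass
class BVPFeatures:
    """Mean pulse amplitude (VP) and mean pulse arrival time (PAT, s)."""

    vp: float
    pat: float
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {"vp": self.vp, "pat": self.pat}


def bvp_features(fiducials: list[tuple], beats: BeatSeries) -> BVPFeatures:
    """Reduce per-beat fiducials to the two BVP features.

    VP = mean(systolic - diastolic); PAT = mean(onset time - preceding R time).
    """
    if len(fiducials) < 3:
        return BVPFeatures(np.nan, np.nan, flags=["too_few_bvp_fiducials"])
    vp = float(np.mean([s[1] - d[1] for s, d, _ in fiducials]))
    r_times = beats.r_times
    pats = []
    for _, _, (t_on, _) in fiducials:
        prev = r_times[r_times <= t_on]
        if len(prev):
            pats.append(t_on - prev[-1])
    return BVPFeatures(vp, float(np.mean(pats)))
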