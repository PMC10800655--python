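"""Seeded multichannel recording generator.

Emulates the statistical structure the downstream analysis assumes: beats with
inverse-Gaussian inter-beat intervals modulated by respiration (RSA), an ECG
waveform rendered at those beat times, a blood-volume pulse arriving a fixed
pulse-arrival-time after each R peak, electrodermal activity as tonic drift
plus discrete skin-conductance responses, a sinusoidal respiration belt,
binocular pupil traces with blinks, and 21-channel EEG whose parietal beta/theta
band-power ratio realizes a per-quadrant attention target.

Class-dependent effects are injected only through the quantities the feature
extractors measure (band powers, SCR rate and rise time, pupil high-frequency
power, cardio-respiratory coupling), not through physiological forward models.
Every generated value is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .protocol import (
    Phase,
    ProtocolTimeline,
    Quadrant,
    Session,
    StimulusWindow,
    ValenceHalf,
    analysis_windows,
    build_timeline,
)
from .cardio import BeatSeries

__all__ = [
    "EffectModel",
    "Rates",
    "RecordingSet",
    "simulate_rr",
    "simulate_channels",
    "make_fixture_suite",
    "make_separable_table",
    "MONTAGE",
]

# 10-20 dry-electrode montage of the 21-channel headset
MONTAGE = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T7", "T8",
    "Pz", "P3", "P4", "P7", "P8",
    "O1", "O2", "A1", "A2",
)

PARIETAL = ("Pz", "P3", "P4", "P7", "P8")

EEG_BANDS = {"delta": (1.0, 3.0), "theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (16.0, 38.0)}


@dataclass(frozen=True)
class Rates:
    """Channel sampling rates in Hz. ``fast()`` lowers the dense channels
    (ECG/BVP by 8, EEG by 3) for quick test runs; the default matches the
    acquisition hardware."""

    ecg: float = 2048.0
    bvp: float = 2048.0
    gsr: float = 256.0
    resp: float = 256.0
    pupil: float = 60.0
    eeg: float = 300.0
    fast_mode: bool = False

    @classmethod
    def fast(cls) -> "Rates":
        return cls(ecg=256.0, bvp=256.0, eeg=100.0, fast_mode=True)

    def as_dict(self) -> dict[str, float]:
        return {
            "ECG": self.ecg, "BVP": self.bvp, "GSR": self.gsr, "RESP": self.resp,
            "PUPIL_L": self.pupil, "PUPIL_R": self.pupil, "EEG": self.eeg,
        }


def _lerp(a: float, b: float, t: float) -> float:
    return a + (b - a) * t


@dataclass
class EffectModel:
    """Planted generative parameters, including the class-dependent effects.

    Directions of the class effects: attention (parietal beta/theta) decreases
    from A1_LV to A4_HV; SCR rate grows with arousal; SCR rise time is longer
    at low valence; pupil high-frequency power grows with arousal; RR-RESP
    coupling is stronger at high valence.
    """

    mu_rr: float = 0.8                       # s, inverse-Gaussian mean inter-beat interval
    ig_shape: float = 1200.0                 # IG shape lambda; var = mu^3 / lambda
    rsa_coupling_by_valence: dict = field(
        default_factory=lambda: {"LOW": 0.015, "HIGH": 0.045})   # s per resp unit
    attention_by_quadrant: dict = field(
        default_factory=lambda: {
            "A1_LV": 1.8, "A1_HV": 1.3, "A4_LV": 0.9, "A4_HV": 0.55})  # parietal beta/theta
    scr_rate_by_arousal: dict = field(
        default_factory=lambda: {"A1": 4.0, "A4": 10.0})         # events / min
    scr_rise_time_by_valence: dict = field(
        default_factory=lambda: {"LOW": 1.2, "HIGH": 0.6})       # s, onset->peak
    scr_amplitude: float = 0.5                                   # uS, median event size
    pupil_hf_gain_by_arousal: dict = field(
        default_factory=lambda: {"A1": 0.04, "A4": 0.12})        # mm RMS in 0.15-0.45 Hz
    pupil_baseline_mm: float = 4.0
    blink_rate_per_min: float = 10.0
    resp_freq_hz: float = 0.25
    resp_amp: float = 1.5
    pat_s: float = 0.25                       # pulse arrival time after R peak
    vp_amp: float = 1.0                       # planted systolic-diastolic amplitude
    noise_sd: dict = field(default_factory=lambda: {
        "ECG": 0.01, "BVP": 0.005, "GSR": 0.003, "RESP": 0.02, "PUPIL": 0.01, "EEG": 0.2})

    def __post_init__(self) -> None:
        if self.mu_rr <= 0 or self.ig_shape <= 0:
            raise ValueError("inverse-Gaussian mean and shape must be positive")
        if any(v <= 0 for v in self.scr_rise_time_by_valence.values()):
            raise ValueError("SCR rise times must be positive")
        if any(v < 0 for v in self.scr_rate_by_arousal.values()):
            raise ValueError("SCR rates must be non-negative")
        missing = {q.value for q in Quadrant if q is not Quadrant.NONE} - set(
            self.attention_by_quadrant)
        if missing:
            raise ValueError(f"attention_by_quadrant missing quadrants: {missing}")

    # -- per-segment parameter lookup ------------------------------------
    def segment_params(self, window: StimulusWindow | None) -> dict:
        """Planted parameters for one timeline segment (None = rest)."""
        if window is None:
            return {
                "coupling": float(np.mean(list(self.rsa_coupling_by_valence.values()))),
                "scr_rate": float(np.mean(list(self.scr_rate_by_arousal.values()))),
                "scr_rise": float(np.mean(list(self.scr_rise_time_by_valence.values()))),
                "pupil_hf": float(np.mean(list(self.pupil_hf_gain_by_arousal.values()))),
                "beta_theta": 1.0,
            }
        half = window.valence_half.value
        a = list(Session).index(window.session) / 3.0  # arousal level in [0, 1]
        att = self.attention_by_quadrant
        return {
            "coupling": self.rsa_coupling_by_valence[half],
            "scr_rate": _lerp(self.scr_rate_by_arousal["A1"], self.scr_rate_by_arousal["A4"], a),
            "scr_rise": self.scr_rise_time_by_valence[half],
            "pupil_hf": _lerp(self.pupil_hf_gain_by_arousal["A1"],
                              self.pupil_hf_gain_by_arousal["A4"], a),
            "beta_theta": _lerp(att[f"A1_{half[0]}V"], att[f"A4_{half[0]}V"], a),
        }


@dataclass
class RecordingSet:
    """One subject-phase bundle of raw channels with their sampling rates."""

    subject_id: str
    phase: Phase
    rates: dict[str, float]
    channels: dict[str, np.ndarray]
    timeline: ProtocolTimeline
    fast_mode: bool = False

    @property
    def duration(self) -> float:
        return self.timeline.phase_duration

    def slice(self, name: str, window: StimulusWindow) -> np.ndarray:
        """Samples of a channel over [t_start, t_end) of a window."""
        r = self.rates[name]
        i0, i1 = int(round(window.t_start * r)), int(round(window.t_end * r))
        x = self.channels[name]
        if i1 > x.shape[-1]:
            raise ValueError("window exceeds the recording")
        return x[..., i0:i1]

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = f"{self.subject_id}_{self.phase.value}"
        np.savez_compressed(directory / f"{stem}.npz", **self.channels)
        sidecar = {
            "subject_id": self.subject_id, "phase": self.phase.value,
            "rates": self.rates, "fast_mode": self.fast_mode,
            "channels": list(self.channels),
        }
        (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
        return directory / f"{stem}.npz"


# ---------------------------------------------------------------------------
# beat generation


def simulate_rr(
    window: StimulusWindow,
    effects: EffectModel,
    resp_signal: np.ndarray,
    seed: int,
    *,
    resp_rate: float = 256.0,
    coupling: float | None = None,
) -> BeatSeries:
    """Draw beats tiling a window with inverse-Gaussian inter-beat intervals.

    The IG mean is modulated additively by the respiration signal at the
    current beat time scaled by the RSA coupling gain; the IG shape is fixed,
    so variance tracks mu^3 / shape.
    """
    if window.duration < 45.0 - 1e-9:
        raise ValueError("window must span at least 45 s")
    if coupling is None:
        coupling = effects.segment_params(window)["coupling"]
    rng = np.random.default_rng(seed)
    t = window.t_start
    times = [t]
    t_resp = np.arange(len(resp_signal)) / resp_rate + window.t_start
    while t < window.t_end:
        r = np.interp(t, t_resp, resp_signal) if len(resp_signal) else 0.0
        mu = effects.mu_rr + coupling * r
        if mu <= 0:
            raise ValueError("modulated IG mean became non-positive")
        rr = stats.invgauss.rvs(mu / effects.ig_shape, scale=effects.ig_shape,
                                random_state=rng)
        t += rr
        times.append(t)
    return BeatSeries(r_times=np.asarray(times))


def _beats_for_phase(timeline: ProtocolTimeline, phase: Phase, effects: EffectModel,
                     resp: np.ndarray, resp_rate: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Beat times over a full phase with window-dependent RSA coupling.

    Returns (r_times, mu_at_beat)."""
    windows = sorted(timeline.windows_of_phase(phase), key=lambda w: w.t_start)

    def params_at(t: float) -> dict:
        for w in windows:
            if w.t_start <= t < w.t_end:
                return effects.segment_params(w)
        return effects.segment_params(None)

    total = timeline.phase_duration
    t_resp = np.arange(len(resp)) / resp_rate
    t = 0.0
    times, mus = [], []
    while t < total:
        p = params_at(t)
        r = np.interp(t, t_resp, resp)
        mu = effects.mu_rr + p["coupling"] * r
        times.append(t)
        mus.append(mu)
        rr = stats.invgauss.rvs(mu / effects.ig_shape, scale=effects.ig_shape,
                                random_state=rng)
        t += rr
    return np.asarray(times), np.asarray(mus)


# ---------------------------------------------------------------------------
# waveform rendering


def _render_ecg(r_times: np.ndarray, duration: float, rate: float,
                noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration * rate))
    x = np.zeros(n)
    # sum-of-Gaussians beat template: P, Q, R, S, T
    comps = [(-0.2, 0.04, 0.10), (-0.025, 0.008, -0.15), (0.0, 0.01, 1.0),
             (0.025, 0.008, -0.20), (0.30, 0.06, 0.30)]
    n_pre = int(round(0.35 * rate))
    tt = (np.arange(n_pre + int(round(0.5 * rate))) - n_pre) / rate  # t=0 on-grid
    template = np.zeros_like(tt)
    for c, w, a in comps:
        template += a * np.exp(-0.5 * ((tt - c) / w) ** 2)
    off = -n_pre
    for r in r_times:
        i = int(round(r * rate)) + off
        j0, j1 = max(i, 0), min(i + len(template), n)
        if j0 < j1:
            x[j0:j1] += template[j0 - i: j1 - i]
    return x + rng.normal(0.0, noise_sd, n)


def _render_bvp(r_times: np.ndarray, duration: float, rate: float, pat: float,
                amp: float, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration * rate))
    x = np.zeros(n)
    # logistic upstroke centred at r + pat (steepest ascent = planted onset),
    # fast exponential decay so successive pulses do not stack
    n_pre = int(round(0.15 * rate))
    tt = (np.arange(n_pre + int(round(0.8 * rate))) - n_pre) / rate  # t=0 on-grid
    rise = 1.0 / (1.0 + np.exp(-tt / 0.012))
    decay = np.exp(-np.maximum(tt - 0.08, 0.0) / 0.12)
    kernel = amp * rise * decay
    off = -n_pre
    for r in r_times:
        i = int(round((r + pat) * rate)) + off
        j0, j1 = max(i, 0), min(i + len(kernel), n)
        if j0 < j1:
            x[j0:j1] += kernel[j0 - i: j1 - i]
    return x + rng.normal(0.0, noise_sd, n)


def _scr_kernel_taus(rise_time: float, tau_decay: float = 3.0) -> tuple[float, float]:
    """Solve the bi-exponential rise constant giving the requested onset-to-peak time."""

    def peak_of(tau_r: float) -> float:
        return tau_r * tau_decay / (tau_decay - tau_r) * np.log(tau_decay / tau_r)

    lo, hi = 1e-4, tau_decay - 1e-4
    tau_r = optimize.brentq(lambda tr: peak_of(tr) - rise_time, lo, hi)
    return tau_r, tau_decay


def _scr_kernel(rise_time: float, rate: float, duration: float = 12.0) -> np.ndarray:
    tau_r, tau_d = _scr_kernel_taus(rise_time)
    t = np.arange(0.0, duration, 1.0 / rate)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return k / k.max()


def _render_gsr(segments, duration: float, rate: float, effects: EffectModel,
                rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    tonic = 2.0 + 0.3 * np.sin(2 * np.pi * t / 240.0) + 0.0005 * t
    x = tonic.copy()
    for t0, t1, params in segments:
        rate_per_s = params["scr_rate"] / 60.0
        n_events = rng.poisson(rate_per_s * (t1 - t0))
        if n_events == 0:
            continue
        kernel = _scr_kernel(params["scr_rise"], rate)
        onsets = np.sort(rng.uniform(t0, t1, n_events))
        for on in onsets:
            amp = effects.scr_amplitude * rng.lognormal(0.0, 0.25)
            i = int(round(on * rate))
            j1 = min(i + len(kernel), n)
            if i < n:
                x[i:j1] += amp * kernel[: j1 - i]
    return x + rng.normal(0.0, effects.noise_sd["GSR"], n)


def _render_resp(duration: float, rate: float, effects: EffectModel,
                 rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = 0.5 * effects.resp_amp * np.sin(2 * np.pi * effects.resp_freq_hz * t)
    return x + rng.normal(0.0, effects.noise_sd["RESP"], n)


def _bandlimited_noise(n: int, rate: float, lo: float, hi: float,
                       rng: np.random.Generator, order: int = 2) -> np.ndarray:
    w = rng.standard_normal(n)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, w)
    s = y.std()
    return y / s if s > 0 else y


def _render_pupil(segments, duration: float, rate: float, effects: EffectModel,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    base = effects.pupil_baseline_mm + 0.1 * np.sin(2 * np.pi * 0.01 * t)
    lf = 0.05 * _bandlimited_noise(n, rate, 0.04, 0.15, rng)
    hf = _bandlimited_noise(n, rate, 0.15, 0.45, rng)
    gain = np.full(n, effects.segment_params(None)["pupil_hf"])
    for t0, t1, params in segments:
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        gain[i0:i1] = params["pupil_hf"]
    common = base + lf + gain * hf
    left = common + rng.normal(0.0, effects.noise_sd["PUPIL"], n)
    right = common + rng.normal(0.0, effects.noise_sd["PUPIL"], n)
    # blinks: diameter collapses below the physiological floor
    n_blinks = rng.poisson(effects.blink_rate_per_min * duration / 60.0)
    for _ in range(n_blinks):
        on = rng.uniform(0.0, duration - 0.3)
        dur = rng.uniform(0.1, 0.25)
        i0, i1 = int(on * rate), int((on + dur) * rate)
        which = rng.random()
        if which < 0.7:
            left[i0:i1] = 0.5
            right[i0:i1] = 0.5
        elif which < 0.85:
            left[i0:i1] = 0.5
        else:
            right[i0:i1] = 0.5
    return left, right


def _render_eeg(segments, duration: float, rate: float, effects: EffectModel,
                rng: np.random.Generator) -> np.ndarray:
    """Per-band filtered noise; parietal beta power scaled per segment to the
    quadrant's beta/theta target (theta power fixed at 1)."""
    n = int(round(duration * rate))
    beta_gain = np.ones(n)
    for t0, t1, params in segments:
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        beta_gain[i0:i1] = np.sqrt(params["beta_theta"])
    powers = {"delta": 1.2, "theta": 1.0, "alpha": 1.0, "beta": 1.0}
    out = np.empty((len(MONTAGE), n))
    for ci, ch in enumerate(MONTAGE):
        x = np.zeros(n)
        for band, (lo, hi) in EEG_BANDS.items():
            comp = _bandlimited_noise(n, rate, lo, hi, rng, order=4)
            g = np.sqrt(powers[band])
            if band == "beta" and ch in PARIETAL:
                comp = comp * beta_gain
            x += g * comp
        out[ci] = x + rng.normal(0.0, effects.noise_sd["EEG"], n)
    return out


# ---------------------------------------------------------------------------
# top-level generation


def _phase_segments(timeline: ProtocolTimeline, phase: Phase, effects: EffectModel):
    return [
        (w.t_start, w.t_end, effects.segment_params(w))
        for w in sorted(timeline.windows_of_phase(phase), key=lambda w: w.t_start)
    ]


def simulate_channels(
    timeline: ProtocolTimeline,
    phase: Phase,
    effects: EffectModel,
    seed: int,
    rates: Rates | None = None,
) -> RecordingSet:
    """Generate all channels of one subject-phase recording.

    Deterministic in (timeline, phase, effects, seed, rates)."""
    rates = rates or Rates()
    phase = Phase(phase)
    phase_idx = list(Phase).index(phase)
    root = np.random.SeedSequence([int(seed), phase_idx])
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    duration = timeline.phase_duration
    segments = _phase_segments(timeline, phase, effects)

    resp = _render_resp(duration, rates.resp, effects, rngs[0])
    r_times, _ = _beats_for_phase(timeline, phase, effects, resp, rates.resp, rngs[1])
    channels = {
        "ECG": _render_ecg(r_times, duration, rates.ecg, effects.noise_sd["ECG"], rngs[2]),
        "BVP": _render_bvp(r_times, duration, rates.bvp, effects.pat_s, effects.vp_amp,
                           effects.noise_sd["BVP"], rngs[2]),
        "GSR": _render_gsr(segments, duration, rates.gsr, effects, rngs[3]),
        "RESP": resp,
        "EEG": _render_eeg(segments, duration, rates.eeg, effects, rngs[4]),
    }
    left, right = _render_pupil(segments, duration, rates.pupil, effects, rngs[5])
    channels["PUPIL_L"], channels["PUPIL_R"] = left, right
    return RecordingSet(
        subject_id=timeline.subject_id, phase=phase, rates=rates.as_dict(),
        channels=channels, timeline=timeline, fast_mode=rates.fast_mode,
    )


def make_fixture_suite(
    n_subjects: int,
    seed: int,
    *,
    effects: EffectModel | None = None,
    rates: Rates | None = None,
    rest_pre_phase: float = 300.0,
    outdir: str | Path | None = None,
) -> tuple[list[RecordingSet], pd.DataFrame]:
    """Generate the full cohort (n_subjects x 3 phases) plus a ground-truth table.

    The ground-truth table lists, per labeled analysis window, every planted
    parameter a downstream extractor is expected to recover. With ``outdir``
    set, recordings are written as compressed array containers with JSON
    sidecars and the ground truth as CSV.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    effects = effects or EffectModel()
    rates = rates or Rates()
    recordings: list[RecordingSet] = []
    rows = []
    for si in range(n_subjects):
        sid = f"S{si + 1:02d}"
        tl = build_timeline(sid, seed, subject_index=si, rest_pre_phase=rest_pre_phase)
        sseed = int(np.random.SeedSequence([int(seed), si, 777]).generate_state(1)[0]
                    % (2**31 - 1))
        for phase in Phase:
            recordings.append(simulate_channels(tl, phase, effects, sseed, rates))
        for w in analysis_windows(tl):
            p = effects.segment_params(w)
            rows.append({
                "subject_id": sid, "phase": w.phase.value, "session": w.session.value,
                "valence_half": w.valence_half.value, "quadrant": w.quadrant.value,
                "mu_rr": effects.mu_rr, "ig_shape": effects.ig_shape,
                "rsa_coupling": p["coupling"], "scr_rate_per_min": p["scr_rate"],
                "scr_rise_time_s": p["scr_rise"], "pupil_hf_gain": p["pupil_hf"],
                "pupil_baseline_mm": effects.pupil_baseline_mm,
                "beta_theta_parietal": p["beta_theta"],
                "pat_s": effects.pat_s, "vp_amp": effects.vp_amp,
                "resp_freq_hz": effects.resp_freq_hz, "resp_amp": effects.resp_amp,
            })
    truth = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            rec.save(outdir)
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    return recordings, truth


# ---------------------------------------------------------------------------
# direct feature-table synthesis (for selection / classification studies)


def make_separable_table(
    n_subjects: int = 22,
    n_features: int = 10,
    n_informative: int = 1,
    separation: float = 2.0,
    seed: int = 0,
    feature_prefix: str = "f",
) -> pd.DataFrame:
    """Draw a labeled observation table directly in feature space.

    Each subject contributes one row per (phase, quadrant) as in the real
    design (12 rows/subject). The first ``n_informative`` features have
    class-dependent means separated by ``separation`` standard deviations;
    the rest are pure noise. Used to study the selection and classification
    stages in isolation from signal processing.
    """
    rng = np.random.default_rng(seed)
    quadrants = [q for q in Quadrant if q is not Quadrant.NONE]
    rows = []
    class_means = {q: i * separation for i, q in enumerate(quadrants)}
    for si in range(n_subjects):
        sid = f"S{si + 1:02d}"
        subj_shift = rng.normal(0.0, 0.3)
        for phase in Phase:
            for q in quadrants:
                vals = rng.standard_normal(n_features)
                vals[:n_informative] += class_means[q] + subj_shift
                row = {"subject_id": sid, "phase": phase.value, "quadrant": q.value}
                row.update({f"{feature_prefix}{i}": vals[i] for i in range(n_features)})
                rows.append(row)
    return pd.DataFrame(rows)
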