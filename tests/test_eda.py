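"""Electrodermal decomposition, SCR detection, feature registry."""

import numpy as np
import pytest

from emophysio.eda import (
    GSR_FEATURE_NAMES,
    decompose_gsr,
    detect_scr,
    gsr_feature_vector,
)
from emophysio.synthetic import _scr_kernel

RATE = 256.0


def _planted_gsr(rise=1.2, onsets=(10, 25, 40), amp=0.5, base=2.0, dur=60.0):
    t = np.arange(0.0, dur, 1.0 / RATE)
    x = np.full_like(t, base)
    k = _scr_kernel(rise, RATE)
    for on in onsets:
        i = int(on * RATE)
        x[i: i + len(k)] += amp * k[: len(x) - i]
    return x


def test_constant_input_has_zero_phasic():
    tonic, phasic = decompose_gsr(np.full(200, 3.3), rate=5.0)
    assert np.allclose(phasic, 0.0, atol=1e-9)
    assert np.allclose(tonic, 3.3, atol=1e-9)
    # through the full filter/decimate chain the residual stays tiny
    _, phasic2 = decompose_gsr(np.full(int(30 * RATE), 3.3), RATE)
    assert np.max(np.abs(phasic2)) < 1e-3


def test_short_segment_rejected():
    with pytest.raises(ValueError):
        decompose_gsr(np.ones(10), rate=5.0)


def _fast_kernel(rate):
    tk = np.arange(0.0, 6.0, 1.0 / rate)
    k = np.exp(-tk / 1.0) - np.exp(-tk / 0.2)
    return k / k.max()


def test_ramp_plus_kernel_decomposition():
    """Tonic tracks the slow ramp; phasic correlates with a planted fast
    transient (short relative to the 4 s median window)."""
    t = np.arange(0.0, 60.0, 1.0 / RATE)
    x = 2.0 + 0.005 * t
    k = _fast_kernel(RATE)
    i = int(25 * RATE)
    x[i: i + len(k)] += 0.5 * k[: len(x) - i]
    tonic, phasic = decompose_gsr(x, RATE)
    t5 = np.arange(len(tonic)) / 5.0
    ramp5 = 2.0 + 0.005 * t5
    # tonic tracks the ramp away from the transient event
    away = (t5 < 20.0) | (t5 > 45.0)
    assert np.max(np.abs(tonic[away] - ramp5[away])) < 0.05
    planted5 = np.zeros_like(phasic)
    k5 = _fast_kernel(5.0)
    j = int(25 * 5)
    planted5[j: j + len(k5)] = 0.5 * k5[: len(planted5) - j]
    assert np.corrcoef(phasic, planted5)[0, 1] >= 0.9
    assert abs(phasic.mean()) < 0.02  # median-centering


class TestDetectSCR:
    def test_subthreshold_gives_no_events(self):
        phasic = 0.005 * np.sin(np.arange(1000) / 50.0)
        assert detect_scr(phasic, 5.0) == []

    def test_planted_events_and_rise_times(self):
        """Five kernels on a slightly negative baseline: five events with
        rise times within one 5 Hz sample of the planted onset-to-peak."""
        rate5 = 5.0
        t = np.arange(0.0, 70.0, 1.0 / rate5)
        phasic = np.full_like(t, -0.02)
        k = _scr_kernel(1.2, rate5, duration=10.0)
        onsets = [5.0, 18.0, 31.0, 44.0, 57.0]
        for on in onsets:
            i = int(on * rate5)
            phasic[i: i + len(k)] += 0.5 * k[: len(phasic) - i]
        events = detect_scr(phasic, rate5)
        assert len(events) == 5
        # measured rise = peak - (0.01+baseline crossing); planted peak at 1.2 s
        for e in events:
            assert e.onset_time < e.peak_time < e.offset_time
            assert e.rise_time == pytest.approx(1.2, abs=1.0 / rate5 + 0.05)

    def test_overlapping_kernels_merge_into_one_event(self):
        rate5 = 5.0
        t = np.arange(0.0, 40.0, 1.0 / rate5)
        phasic = np.full_like(t, -0.02)
        k = _scr_kernel(0.8, rate5, duration=10.0)
        for on in (10.0, 12.0):  # no return below 0.0 in between
            i = int(on * rate5)
            phasic[i: i + len(k)] += 0.5 * k[: len(phasic) - i]
        events = detect_scr(phasic, rate5)
        assert len(events) == 1
        span = (events[0].onset_time, events[0].offset_time)
        peak_val = events[0].amplitude
        i0, i1 = int(span[0] * rate5), int(span[1] * rate5)
        assert peak_val == pytest.approx(float(phasic[i0:i1].max()), abs=1e-12)


class TestFeatureVector:
    def test_registry_has_17_stable_names(self):
        feats, flags = gsr_feature_vector(_planted_gsr(), RATE)
        assert tuple(feats) == GSR_FEATURE_NAMES and len(feats) == 17
        assert flags == []
        assert feats["gsr_scr_count"] >= 1

    def test_rise_time_ordering_low_vs_high_valence(self):
        slow, _ = gsr_feature_vector(_planted_gsr(rise=1.2), RATE)
        fast, _ = gsr_feature_vector(_planted_gsr(rise=0.6), RATE)
        assert slow["gsr_peaks_rise_time"] > fast["gsr_peaks_rise_time"]

    def test_offset_shift_equivariance(self):
        a, _ = gsr_feature_vector(_planted_gsr(base=2.0), RATE)
        b, _ = gsr_feature_vector(_planted_gsr(base=3.5), RATE)
        shifted = {"gsr_mean", "gsr_tonic_mean"}
        for name in GSR_FEATURE_NAMES:
            if name in shifted:
                assert b[name] - a[name] == pytest.approx(1.5, abs=0.01)
            else:
                assert b[name] == pytest.approx(a[name], abs=1e-6)

    def test_zero_scr_flagged(self):
        feats, flags = gsr_feature_vector(np.full(int(50 * RATE), 2.0), RATE)
        assert "no_scr_detected" in flags
        for name in ("gsr_scr_amp_mean", "gsr_scr_amp_sum", "gsr_peaks_rise_time"):
            assert feats[name] == 0.0
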