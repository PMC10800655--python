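"""R-peak detection, inverse-Gaussian point-process HRV, BVP fiducials."""

import numpy as np
import pytest
from scipy import stats

from emophysio.cardio import (
    HRV_FIELDS,
    BeatSeries,
    bvp_features,
    bvp_fiducials,
    detect_r_peaks,
    fit_ig_pointprocess,
    ig_rescaled_ks,
)
from emophysio.synthetic import _render_bvp, _render_ecg

RATE = 2048.0


def _planted_beats(n=60, rr=0.75):
    t = np.arange(n) * rr
    return t


def test_beat_series_validation():
    with pytest.raises(ValueError):
        BeatSeries([0.0, 0.5, 0.4])
    b = BeatSeries([0.0, 0.8, 1.6])
    assert np.allclose(b.rr, [0.8, 0.8])


class TestPanTompkins:
    def test_planted_beats_recovered_within_10ms(self, rng):
        planted = _planted_beats()
        ecg = _render_ecg(planted, 46.0, RATE, 0.01, rng)
        det = detect_r_peaks(ecg, RATE).r_times
        assert len(det) == len(planted)
        errs = [np.min(np.abs(det - p)) for p in planted]
        assert max(errs) <= 0.010

    def test_scale_invariance(self, rng):
        ecg = _render_ecg(_planted_beats(), 46.0, RATE, 0.01, rng)
        a = detect_r_peaks(ecg, RATE)
        b = detect_r_peaks(123.4 * ecg, RATE)
        assert np.array_equal(a.r_times, b.r_times)

    def test_flat_signal_gives_no_beats(self):
        with pytest.warns(UserWarning):
            beats = detect_r_peaks(np.zeros(int(20 * RATE)), RATE)
        assert len(beats) == 0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(1000), rate=100.0)


class TestIGPointProcess:
    def test_mu_recovery(self):
        """Constant-mean IG simulation over 45 s recovers mu within 0.02 s."""
        mu, lam = 0.8, 1200.0
        for s in range(5):
            rr = stats.invgauss.rvs(mu / lam, scale=lam, size=56,
                                    random_state=np.random.default_rng(s))
            beats = BeatSeries(np.concatenate([[0.0], np.cumsum(rr)]))
            fit = fit_ig_pointprocess(beats, order=8)
            assert abs(fit.mu_rr - mu) < 0.02

    def test_nine_fields(self):
        rr = stats.invgauss.rvs(0.8 / 1200, scale=1200, size=40,
                                random_state=np.random.default_rng(0))
        fit = fit_ig_pointprocess(BeatSeries(np.concatenate([[0], np.cumsum(rr)])))
        d = fit.as_dict()
        assert tuple(d) == HRV_FIELDS and len(d) == 9
        assert fit.lfn + fit.hfn == pytest.approx(1.0, abs=1e-9)
        assert all(d[k] >= 0 for k in ("vlf", "lf", "hf", "tot"))
        assert fit.tot >= fit.vlf + fit.lf + fit.hf - 1e-9

    def test_rsa_modulation_gives_hf_dominance(self):
        """RR modulated at 0.25 Hz puts the spectral mass in HF."""
        rng = np.random.default_rng(2)
        mu, lam = 0.8, 1200.0
        t, times = 0.0, [0.0]
        while t < 45.0:
            m = mu + 0.05 * np.sin(2 * np.pi * 0.25 * t)
            t += stats.invgauss.rvs(m / lam, scale=lam, random_state=rng)
            times.append(t)
        fit = fit_ig_pointprocess(BeatSeries(np.array(times)), order=8)
        assert fit.hfn > fit.lfn

    def test_order_zero_matches_closed_form_mle(self):
        """With no history and no forgetting, the fit equals the IG MLE."""
        rr = stats.invgauss.rvs(0.8 / 1200, scale=1200, size=60,
                                random_state=np.random.default_rng(3))
        beats = BeatSeries(np.concatenate([[0.0], np.cumsum(rr)]))
        fit = fit_ig_pointprocess(beats, order=0, forgetting=1.0)
        mu_hat = rr.mean()
        lam_hat = 1.0 / np.mean(1.0 / rr - 1.0 / mu_hat)
        assert fit.mu_rr == pytest.approx(mu_hat, rel=1e-4)
        assert fit.lam == pytest.approx(lam_hat, rel=1e-3)
        assert fit.sigma2 == pytest.approx(mu_hat**3 / lam_hat, rel=1e-3)

    def test_time_rescaling_ks(self):
        """Rescaled intervals pass a KS uniformity test in >= 90% of seeds."""
        mu, lam = 0.8, 1200.0
        passed = 0
        n_seeds = 20
        for s in range(n_seeds):
            rr = stats.invgauss.rvs(mu / lam, scale=lam, size=56,
                                    random_state=np.random.default_rng(500 + s))
            beats = BeatSeries(np.concatenate([[0.0], np.cumsum(rr)]))
            fit = fit_ig_pointprocess(beats, order=8)
            if ig_rescaled_ks(beats, fit, order=8) > 0.05:
                passed += 1
        assert passed >= 0.9 * n_seeds

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            fit_ig_pointprocess(BeatSeries(np.arange(6) * 0.8), order=8)


class TestBVP:
    def _setup(self, rng, pat=0.25, amp=1.0, n=50):
        planted = _planted_beats(n)
        bvp = _render_bvp(planted, planted[-1] + 1.0, RATE, pat, amp, 0.002, rng)
        return BeatSeries(planted), bvp

    def test_planted_amplitude_recovered(self, rng):
        beats, bvp = self._setup(rng)
        fid, skipped = bvp_fiducials(bvp, RATE, beats)
        feats = bvp_features(fid, beats)
        assert feats.vp == pytest.approx(1.0, rel=0.05)
        assert len(fid) <= len(beats) - 1

    def test_planted_pat_within_one_sample(self, rng):
        beats, bvp = self._setup(rng)
        fid, _ = bvp_fiducials(bvp, RATE, beats)
        feats = bvp_features(fid, beats)
        assert abs(feats.pat - 0.25) <= 1.0 / 250.0

    def test_amplitude_scaling_linearity(self, rng):
        beats, bvp = self._setup(rng, amp=1.0)
        f1 = bvp_features(*[bvp_fiducials(bvp, RATE, beats)[0]][:1], beats)
        f2 = bvp_features(bvp_fiducials(2.0 * bvp, RATE, beats)[0], beats)
        assert f2.vp == pytest.approx(2.0 * f1.vp, rel=1e-6)
        assert f2.pat == pytest.approx(f1.pat, abs=1e-9)

    def test_constant_bvp_skips_all_beats(self):
        beats = BeatSeries(_planted_beats(20))
        fid, skipped = bvp_fiducials(np.ones(int(16 * RATE)), RATE, beats)
        assert fid == []
        assert skipped == len(beats) - 1

    def test_too_few_fiducials_flagged(self):
        feats = bvp_features([], BeatSeries(np.array([0.0, 0.8])))
        assert np.isnan(feats.vp) and "too_few_bvp_fiducials" in feats.flags

    def test_output_is_two_features(self, rng):
        beats, bvp = self._setup(rng)
        fid, _ = bvp_fiducials(bvp, RATE, beats)
        assert len(bvp_features(fid, beats).as_dict()) == 2
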