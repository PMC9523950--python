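"""Laminar-recording analysis: VEP, CSD, MUA, Morse scalograms."""

import numpy as np
import pytest
from scipy import signal

from fhmnet.ephys import (LaminarRecording, csd, morse_cwt, mua_extract,
                          scalogram_modulation, vep_average, vep_features)
from fhmnet.measures import psd_welch, zscore


def _recording(data, reversals, fs=1000.0, prestim=(0.0, 1000.0)):
    return LaminarRecording(data=data, fs=fs,
                            reversal_times=np.asarray(reversals, dtype=float),
                            prestim_span=prestim)


def _template(n1_amp=-0.3, n1_lat=80.0, p2_amp=0.15, p2_lat=150.0, n=500):
    t = np.arange(n, dtype=float)
    v = n1_amp * np.exp(-0.5 * ((t - n1_lat) / 15.0) ** 2)
    if p2_amp:
        v += p2_amp * np.exp(-0.5 * ((t - p2_lat) / 25.0) ** 2)
    return t, v


class TestVEPAverage:
    def test_identical_epochs_average_to_one_epoch(self):
        _, tpl = _template()
        x = np.zeros(6000)
        revs = [1000.0, 2000.0, 3000.0, 4000.0]
        for r in revs:
            x[int(r):int(r) + 500] += tpl
        t, v = vep_average(_recording(x[None, :], revs), 0, window=(0, 500))
        assert np.allclose(v, tpl)

    def test_noise_averages_down_as_sqrt_trials(self):
        rng = np.random.default_rng(0)
        _, tpl = _template()
        n_tr = 30
        x = 0.1 * rng.standard_normal(2000 + n_tr * 1000)
        revs = [2000.0 + 1000.0 * i for i in range(n_tr)]
        for r in revs:
            x[int(r):int(r) + 500] += tpl
        t, v = vep_average(_recording(x[None, :], revs), 0, window=(0, 500))
        assert np.max(np.abs(v - tpl)) < 5 * 0.1 / np.sqrt(n_tr)

    def test_shuffled_alignment_destroys_phase_locking(self):
        rng = np.random.default_rng(1)
        _, tpl = _template()
        n_tr = 40
        x = np.zeros(2000 + n_tr * 1000)
        revs = [2000.0 + 1000.0 * i for i in range(n_tr)]
        for r in revs:
            x[int(r):int(r) + 500] += tpl
        fake = 2000.0 + rng.uniform(0, n_tr * 1000 - 600, size=n_tr)
        t, v = vep_average(_recording(x[None, :], np.sort(fake)), 0,
                           window=(0, 500))
        assert np.abs(v).max() < 0.3 * np.abs(tpl).max()

    def test_out_of_bounds_epochs_dropped_with_warning(self):
        x = np.zeros(3000)
        with pytest.warns(UserWarning):
            t, v = vep_average(_recording(x[None, :], [500.0, 2900.0]), 0,
                               window=(0, 500))

    def test_needs_two_reversals(self):
        with pytest.raises(ValueError):
            vep_average(_recording(np.zeros((1, 2000)), [100.0]), 0)


class TestVEPFeatures:
    def test_recovers_constructed_n1(self):
        t, v = _template(n1_amp=-0.3, n1_lat=80.0)
        f = vep_features(t, v)
        # the P2 lobe overlaps the N1 trough by ~0.003 mV
        assert f.n1_amp == pytest.approx(-0.3, abs=5e-3)
        assert f.n1_latency == pytest.approx(80.0, abs=1.0)
        assert f.has_p2
        assert f.p2_minus_n1 == pytest.approx(0.45, abs=0.01)

    def test_downslope_of_linear_ramp(self):
        # linear descent to N1 = -0.4 mV over 40 ms: slope -10 mV/s
        t = np.arange(500, dtype=float)
        v = np.where(t < 40, -0.01 * t, -0.4)
        v = np.where(t > 150, -0.4 + 0.002 * (t - 150), v)
        f = vep_features(t, v, n1_window=(20, 150))
        assert f.downslope == pytest.approx(-10.0, rel=0.05)

    def test_dc_offset_invariance(self):
        t, v = _template()
        a, b = vep_features(t, v), vep_features(t, v + 3.7)
        assert a.n1_amp == pytest.approx(b.n1_amp)
        assert a.n1_latency == b.n1_latency
        assert a.downslope == pytest.approx(b.downslope)

    def test_absent_p2_flagged(self):
        t, v = _template(p2_amp=0.0)
        f = vep_features(t, v)
        assert not f.has_p2
        assert np.isnan(f.p2_minus_n1)

    def test_no_negative_deflection_rejected(self):
        t = np.arange(400, dtype=float)
        with pytest.raises(ValueError):
            vep_features(t, np.full(400, 0.2))


class TestCSD:
    def test_depth_linear_potential_gives_zero(self):
        z = np.arange(16)[:, None]
        data = np.repeat(0.5 * z.astype(float), 200, axis=1)
        rec = _recording(data, [])
        prof = csd(rec, gaussian_sd_mm=0.0)
        assert np.allclose(prof.csd, 0.0, atol=1e-9)

    def test_depth_quadratic_potential_constant_csd(self):
        a = 0.01  # mV per channel^2
        z = np.arange(16, dtype=float)
        data = np.repeat((a * z ** 2)[:, None], 100, axis=1)
        prof = csd(_recording(data, []), gaussian_sd_mm=0.0)
        h_m = 50e-6
        want = -0.3 * (2 * a * 1e-3) / h_m ** 2 * (50e-6 / 1) ** 0  # -sigma * 2a/h^2
        want = -0.3 * 2 * a * 1e-3 / h_m ** 2 * h_m ** 2 / h_m ** 2
        # second difference of a*z^2 over unit channel step is exactly 2a
        want = -0.3 * (2 * a * 1e-3) / (50e-6) ** 2
        assert np.allclose(prof.csd, want, rtol=1e-9)

    def test_synthetic_sink_localized(self):
        rng = np.random.default_rng(2)
        n_ch, n_tr = 16, 20
        x = 0.02 * rng.standard_normal((n_ch, 2000 + n_tr * 1000))
        revs = [2000.0 + 1000.0 * i for i in range(n_tr)]
        t, tpl = _template(n1_amp=-0.4, n1_lat=40.0, p2_amp=0.0)
        prof_depth = np.exp(-0.5 * ((np.arange(n_ch) - 8) / 1.5) ** 2)
        for r in revs:
            x[:, int(r):int(r) + 500] += prof_depth[:, None] * tpl[None, :]
        prof = csd(_recording(x, revs))
        assert prof.layer4_channel == 8

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            csd(_recording(np.zeros((2, 100)), []))


class TestMUA:
    def _carrier(self, env, fs=1000.0, seed=3):
        rng = np.random.default_rng(seed)
        sos = signal.butter(3, [200, 450], btype="bandpass", fs=fs,
                            output="sos")
        x = signal.sosfilt(sos, rng.standard_normal(env.size))
        return x * np.sqrt(env)

    def _burst_modulation(self, gain, n_tr=150, seed=4):
        """Mean normalized MUA over the planted burst window [50, 70] ms."""
        n = 6000 + n_tr * 1000
        t_all = np.arange(n)
        revs = [5000.0 + 1000.0 * i for i in range(n_tr)]
        env = np.ones(n)
        for r in revs:
            env += gain * np.exp(-0.5 * ((t_all - r - 60) / 20.0) ** 2)
        x = self._carrier(env, seed=seed)
        t, mua = mua_extract(x, 1000.0, revs)
        window = (t >= 50.0) & (t <= 70.0)
        return t, mua, float(mua[window].mean())

    def test_stationary_signal_flat(self):
        n_tr = 150
        env = np.ones(6000 + n_tr * 1000)
        x = self._carrier(env)
        revs = [5000.0 + 1000.0 * i for i in range(n_tr)]
        t, mua = mua_extract(x, 1000.0, revs)
        # envelope-power estimation noise only
        assert np.abs(mua).max() < 35.0  # percent

    def test_power_doubling_burst_detected(self):
        t, mua, at_burst = self._burst_modulation(gain=1.0)
        assert abs(t[np.argmax(mua)] - 60.0) < 20.0
        # doubling the envelope power reads out as ~+100% modulation
        assert at_burst == pytest.approx(100.0, rel=0.3)

    def test_modulation_linear_in_burst_power(self):
        _, _, half = self._burst_modulation(gain=0.5, seed=5)
        _, _, full = self._burst_modulation(gain=1.0, seed=5)
        assert full / half == pytest.approx(2.0, rel=0.3)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            mua_extract(np.zeros(1000), 500.0, [100.0])


class TestMorse:
    def test_tone_ridge_frequency(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 60.0 * t)
        freqs, W = morse_cwt(x, 1000.0)
        power = (np.abs(W) ** 2).mean(axis=1)
        assert freqs[np.argmax(power)] == pytest.approx(60.0, rel=0.06)

    def test_band_energy_tracks_welch(self):
        """Relative band energies of the scalogram match Welch within 10%
        after a single global scaling (stationary two-tone signal)."""
        rng = np.random.default_rng(5)
        t = np.arange(30000) / 1000.0
        x = (np.sin(2 * np.pi * 25.0 * t) + 0.7 * np.sin(2 * np.pi * 80.0 * t)
             + 0.1 * rng.standard_normal(t.size))
        freqs, W = morse_cwt(x, 1000.0)
        scal = (np.abs(W) ** 2).mean(axis=1)
        f, p = psd_welch(x, fs=1000.0)
        def band(fr, v, lo, hi):
            sel = (fr >= lo) & (fr <= hi)
            return v[sel]
        # energy ratio of the two tones: scalogram ridge power vs
        # Welch band-integrated power must agree within 10%
        ratio_scal = band(freqs, scal, 20, 30).max() / band(freqs, scal, 70, 90).max()
        ratio_welch = band(f, p, 20, 30).sum() / band(f, p, 70, 90).sum()
        assert ratio_scal == pytest.approx(ratio_welch, rel=0.10)

    def test_stationary_modulation_near_zero(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 40000))
        revs = [5000.0 + 1000.0 * i for i in range(30)]
        rec = _recording(x, revs, prestim=(0.0, 5000.0))
        sm = scalogram_modulation(rec, 0)
        assert np.abs(np.nanmean(sm.mod)) < 0.1

    def test_post_reversal_tone_makes_positive_ridge(self):
        rng = np.random.default_rng(7)
        n = 45000
        x = rng.standard_normal(n)
        t_all = np.arange(n)
        revs = [5000.0 + 1000.0 * i for i in range(38)]
        for r in revs:
            seg = (t_all >= r) & (t_all < r + 200)
            x[seg] += 1.5 * np.sin(2 * np.pi * 60.0 * (t_all[seg] - r) / 1000.0)
        rec = _recording(x[None, :], revs, prestim=(0.0, 5000.0))
        sm = scalogram_modulation(rec, 0)
        fsel = (sm.freqs >= 50) & (sm.freqs <= 72)
        post = (sm.times > 20) & (sm.times < 180)
        pre = sm.times < 0
        assert sm.mod[np.ix_(fsel, post)].mean() > 5 * np.abs(
            sm.mod[np.ix_(fsel, pre)].mean())

    def test_missing_prestim_span_rejected(self):
        rec = _recording(np.zeros((1, 2000)), [500.0], prestim=(0.0, 0.0))
        with pytest.raises(ValueError):
            scalogram_modulation(rec, 0)
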