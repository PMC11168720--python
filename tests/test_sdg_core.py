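"""The coupling model: IPFM closed forms, modulation assembly, and the
forward-inverse round trip of both coupling estimators (the master oracle
of the package)."""

import numpy as np
import pytest

from bhi import band_power, sdg_core, synthetic_data
from bhi.sdg_core import HtBParams, IPFMParams
from bhi.types import BandPowerSeries, get_band


def _series(name, t, power_or_amp, amplitude=False, channel="Cz", valid=None):
    power = power_or_amp**2 / 2.0 if amplitude else power_or_amp
    return BandPowerSeries(band=get_band(name), t_s=t, power=power,
                           valid=valid, channel=channel)


class TestIPFM:
    def test_constant_rate_closed_forms(self):
        for bpm, rr in ((60.0, 1.0), (75.0, 0.8)):
            beats = sdg_core.ipfm_generate(
                lambda t: np.zeros_like(t), IPFMParams(hr_ref_bpm=bpm), 30.0
            )
            assert np.allclose(np.diff(beats), rr, atol=1e-6)
            assert np.allclose(beats[0], rr, atol=1e-6)

    def test_hf_modulation_dominates_hf_band(self):
        params = IPFMParams(hr_ref_bpm=60.0)
        beats = sdg_core.ipfm_generate(
            lambda t: 0.05 * np.sin(2 * np.pi * 0.25 * t), params, 300.0
        )
        from bhi.preprocess import RRSeries, interpolate_rr

        rrs = interpolate_rr(RRSeries.from_beats(beats))
        hf = band_power.hrv_band_power(rrs.rr4hz, "HF")
        lf = band_power.hrv_band_power(rrs.rr4hz, "LF")
        assert (np.median(hf.power[hf.valid])
                > 3 * np.median(lf.power[lf.valid]))

    def test_mean_rate_converges_to_reference(self):
        rng = np.random.default_rng(0)
        t_grid = np.arange(600.0)
        c = 0.03 * (1 + 0.3 * rng.standard_normal(600)).clip(0, None)
        m = sdg_core.modulation_from_eq1(c, c, t_grid, IPFMParams())
        beats = sdg_core.ipfm_generate(m, IPFMParams(hr_ref_bpm=70.0), 600.0)
        bpm = 60.0 * len(beats) / beats[-1]
        assert abs(bpm - 70.0) / 70.0 < 0.01

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            sdg_core.ipfm_generate(lambda t: -1.5 * np.ones_like(t),
                                   IPFMParams(), 10.0)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            IPFMParams(hr_ref_bpm=10.0)
        with pytest.raises(ValueError):
            IPFMParams(c_lf0=-0.1)
        with pytest.raises(ValueError):
            HtBParams(eta={b: 1.2 for b in ("delta", "theta", "alpha",
                                            "beta")})


class TestModulation:
    def test_single_tone_when_one_amplitude_zero(self):
        t = np.arange(100.0)
        params = IPFMParams()
        m = sdg_core.modulation_from_eq1(np.zeros(100), np.full(100, 0.2),
                                         t, params)
        tt = np.linspace(10, 90, 5000)
        expect = 0.2 * np.sin(params.omega_hf * tt)
        assert np.allclose(m(tt), expect, atol=1e-9)

    def test_zero_amplitudes_zero_modulation(self):
        t = np.arange(50.0)
        m = sdg_core.modulation_from_eq1(np.zeros(50), np.zeros(50), t,
                                         IPFMParams())
        assert np.allclose(m(np.linspace(0, 49, 999)), 0.0)

    def test_step_change_tracks_within_one_grid_step(self):
        t = np.arange(100.0)
        c_hf = np.where(t < 50, 0.0, 0.3)
        m = sdg_core.modulation_from_eq1(np.zeros(100), c_hf, t,
                                         IPFMParams())
        assert np.all(np.abs(m(np.linspace(0, 48.9, 100))) <= 0.3 * 0.1 + 1e-12)
        tt = np.linspace(51, 80, 500)
        assert np.max(np.abs(m(tt))) > 0.25

    def test_negative_amplitude_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError, match="nonnegative"):
            sdg_core.modulation_from_eq1(-np.ones(10), np.zeros(10), t,
                                         IPFMParams())


class TestEstimators:
    def test_bth_noiseless_exact(self):
        t, y, drv, _ = synthetic_data.simulate_coupled_series(
            "BtH", 600, coeff=0.3, intercept=2.0, seed=1
        )
        r = sdg_core.estimate_bth(
            _series("LF", t, y, amplitude=True),
            _series("theta", t, drv),
        )
        ok = ~r.degenerate
        assert ok.sum() > 100
        assert np.nanmax(np.abs(r.coeff[ok] - 0.3) / 0.3) < 1e-9
        assert np.nanmax(np.abs(r.extra[ok] - 2.0)) < 1e-9

    def test_htb_noiseless_exact(self):
        t, y, drv, _ = synthetic_data.simulate_coupled_series(
            "HtB", 600, coeff=0.5, eta=0.9, seed=2
        )
        r = sdg_core.estimate_htb(
            _series("delta", t, y, amplitude=True),
            _series("LF", t, drv),
        )
        ok = ~r.degenerate
        assert np.nanmax(np.abs(r.coeff[ok] - 0.5) / 0.5) < 1e-9
        assert np.nanmax(np.abs(r.extra[ok] - 0.9)) < 1e-9

    def test_bth_noisy_within_sampling_error(self):
        """Monte-Carlo: noisy OLS estimates stay within +-3 standard
        errors of the true coupling, averaged over 100 seeds."""
        true = 0.3
        # noise at 10% of the response range (~ coeff * driver spread)
        noise_std = 0.06
        ests = []
        for seed in range(100):
            t, y, drv, _ = synthetic_data.simulate_coupled_series(
                "BtH", 600, coeff=true, intercept=2.0,
                noise_std=noise_std, seed=seed,
            )
            r = sdg_core.estimate_bth(
                _series("LF", t, y, amplitude=True),
                _series("theta", t, drv), window_s=60.0,
            )
            ok = ~r.degenerate
            ests.append(np.nanmean(r.coeff[ok]))
        mean_est = np.mean(ests)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean_est - true) < 3 * se + 0.05 * true

    def test_htb_tracks_slow_coefficient_ramp(self):
        ramp = np.linspace(0.2, 0.8, 600)
        t, y, drv, kser = synthetic_data.simulate_coupled_series(
            "HtB", 600, coeff=ramp, eta=0.8, driver_tau=5.0, seed=3
        )
        r = sdg_core.estimate_htb(
            _series("delta", t, y, amplitude=True),
            _series("LF", t, drv), window_s=60.0,
        )
        ok = ~r.degenerate
        truth = np.interp(r.t_s[ok], t, kser)
        assert np.corrcoef(r.coeff[ok], truth)[0, 1] >= 0.9

    def test_constant_driver_flagged_degenerate(self):
        t = np.arange(200.0)
        y = 2.0 + 0.1 * np.sin(0.3 * t)
        r = sdg_core.estimate_bth(
            _series("LF", t, y, amplitude=True),
            _series("theta", t, np.full(200, 5.0)),
        )
        assert np.all(r.degenerate)
        assert np.all(np.isnan(r.coeff))

    def test_zero_cardiac_drive_keeps_ar_gain(self):
        rng = np.random.default_rng(4)
        y = np.zeros(300)
        y[0] = 1.0
        for k in range(1, 300):
            y[k] = 0.9 * y[k - 1] + 0.1 + 0.02 * rng.standard_normal()
        r = sdg_core.estimate_htb(
            _series("delta", np.arange(300.0), y, amplitude=True),
            _series("LF", np.arange(300.0), np.zeros(300)),
        )
        assert np.all(r.degenerate)
        assert np.all(np.isnan(r.coeff))
        ok = np.isfinite(r.extra)
        assert ok.any()
        assert np.nanmedian(np.abs(r.extra[ok])) < 1.05

    def test_scale_equivariance(self):
        t, y, drv, _ = synthetic_data.simulate_coupled_series(
            "BtH", 400, coeff=0.4, seed=9
        )
        r1 = sdg_core.estimate_bth(_series("LF", t, y, amplitude=True),
                                   _series("theta", t, drv))
        r2 = sdg_core.estimate_bth(_series("LF", t, y, amplitude=True),
                                   _series("theta", t, 10.0 * drv))
        ok = ~r1.degenerate & ~r2.degenerate
        assert np.allclose(r2.coeff[ok], r1.coeff[ok] / 10.0, rtol=1e-6)

    def test_misaligned_grids_rejected(self):
        t = np.arange(200.0)
        a = _series("delta", t, np.ones(200))
        b = _series("LF", t + 0.5, np.ones(200))
        with pytest.raises(ValueError, match="grid"):
            sdg_core.estimate_htb(a, b)

    @pytest.mark.parametrize("n,win,step", [(600, 120, 1), (600, 15, 1),
                                            (300, 30, 5), (100, 10, 3)])
    def test_series_length_contract(self, n, win, step):
        t = np.arange(float(n))
        rng = np.random.default_rng(0)
        drv = 1.0 + 0.3 * rng.standard_normal(n).clip(-2, 2)
        y = 1.0 + 0.2 * drv
        r = sdg_core.estimate_bth(
            _series("LF", t, y, amplitude=True), _series("theta", t, drv),
            window_s=float(win), step_s=float(step),
        )
        assert r.coeff.size == sdg_core.n_windows(n, win, step)


class TestComputeBHIWindow:
    def test_full_grid_combinatorics(self, small_session):
        rec = small_session.recording
        fs = rec.fs
        n = int(140 * fs)
        rr4 = 0.85 + 0.02 * np.sin(2 * np.pi * 0.25 * np.arange(0, 140, 0.25))
        series = sdg_core.compute_bhi_window(
            rec.eeg[:3, :n], fs, rr4, rec.channel_labels[:3],
            window_s=40.0,
        )
        assert len(series) == 3 * 16
        labels = {(s.direction, s.eeg_band, s.hrv_band) for s in series}
        assert len(labels) == 16
        for s in series:
            assert s.t_s.size == series[0].t_s.size

    def test_band_subset(self, small_session):
        rec = small_session.recording
        fs = rec.fs
        n = int(140 * fs)
        rr4 = 0.85 + 0.02 * np.sin(2 * np.pi * 0.1 * np.arange(0, 140, 0.25))
        series = sdg_core.compute_bhi_window(
            rec.eeg[:2, :n], fs, rr4, rec.channel_labels[:2],
            window_s=40.0, eeg_bands=("delta",), hrv_bands=("LF",),
        )
        assert len(series) == 2 * 2
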