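import numpy as np
import pytest
from scipy import optimize

from disuse.hrf import FWHM_PER_SD, double_gamma, hrf_peak_time
from disuse.pulse_detect import PulseEvent
from disuse.pulse_model import (
    FIRCurve,
    HRFFit,
    disp_to_fwhm,
    fir_estimate,
    fir_features,
    fit_hrf_at_pulse,
    normalize_amplitudes,
    pulse_maps,
    top_fraction_mask,
)

from conftest import make_run


def event(frame=100, tr=1.1, run_id="r"):
    return PulseEvent(run_id=run_id, peak_frame=frame,
                      peak_time_s=frame * tr, z_diff=5.0, z_left=5.0)


class TestFitHRF:
    def test_noise_free_kernel_recovered(self):
        tr = 1.1
        t = np.arange(240) * tr
        ev = event(100, tr)
        y = 2.0 * double_gamma(t - (ev.peak_time_s - 5.0), 5.0, 1.0)
        fit = fit_hrf_at_pulse(y, t, ev)
        assert fit.converged
        assert fit.time_to_peak_s == pytest.approx(5.0, abs=0.05)
        assert fit.peak_disp_s == pytest.approx(1.0, abs=0.05)
        assert fit.amplitude == pytest.approx(2.0, rel=0.05)

    def test_white_noise_convergence_rate_low(self, rng):
        tr = 1.1
        t = np.arange(240) * tr
        conv = 0
        for i in range(100):
            y = rng.standard_normal(240)
            conv += fit_hrf_at_pulse(y, t, event(100, tr)).converged
        assert conv <= 20

    def test_zero_signal_not_converged(self):
        tr = 1.1
        t = np.arange(240) * tr
        fit = fit_hrf_at_pulse(np.zeros(240), t, event(100, tr))
        assert not fit.converged

    def test_optimizer_failure_returns_nonconverged(self):
        # two-frame window: far too few points, must not raise
        t = np.arange(4) * 1.1
        fit = fit_hrf_at_pulse(np.array([0.0, 1.0, 0.0, 0.0]), t, event(1))
        assert not fit.converged


class TestPulseMaps:
    def _fit(self, conv, peak=10.0, amp=1.0):
        return HRFFit(amplitude=amp, onset_shift_s=0.0, time_to_peak_s=5.0,
                      peak_disp_s=1.0, undershoot_ratio=0.1, converged=conv,
                      rss=0.1, peak_time_s=peak)

    def test_all_converged_gives_detectability_one(self):
        fits = [[self._fit(True), self._fit(True)]]
        maps = pulse_maps(fits, np.array([9.0, 9.5]))
        assert maps.detectability[0] == 1.0
        assert maps.latency_s[0] == pytest.approx(0.75)

    def test_top_fraction_keeps_exact_count(self, rng):
        values = rng.standard_normal(100)
        mask = top_fraction_mask(values, 0.20)
        assert mask.sum() == 20
        assert values[mask].min() >= np.sort(values)[-20]

    def test_latency_threshold_in_display_mask(self):
        det = np.linspace(0, 1, 10)
        lat = np.array([0.5] * 5 + [2.0] * 5)
        maps = pulse_maps(
            [[self._fit(True, peak=9.0 + l)] for l in lat], np.array([9.0]))
        m = maps.display_mask(top_fraction=0.5, latency_max_s=1.1)
        assert not m[5:].any()          # latencies beyond 1.1 s excluded


class TestFIR:
    def test_single_noise_free_event_recovers_waveform(self):
        tr = 1.1
        T = 240
        t = np.arange(T) * tr
        ev = event(100, tr)
        wave = 3.0 * double_gamma(t - ev.peak_time_s + 5.0)
        run = make_run(wave[None, :], tr=tr, session_id="r")
        curves = fir_estimate([run], [ev] * 5, min_events=5)
        c = curves[0]
        lag0 = np.argmin(np.abs(c.lags_s))
        # deconvolution identity: curve reproduces the waveform at the
        # event peak (AR(1) pre-whitening leaves sub-percent coupling)
        assert c.values[lag0] == pytest.approx(wave[100], abs=0.01 * wave.max())
        inwin = (t >= ev.peak_time_s - 17.6) & (t <= ev.peak_time_s + 15.4)
        # full curve reproduces the waveform across the window
        np.testing.assert_allclose(
            c.values[np.searchsorted(c.lags_s, t[inwin] - ev.peak_time_s)],
            wave[inwin] - wave.mean(), atol=0.05 * np.abs(wave).max())

    def test_two_events_same_curve(self, rng):
        tr = 1.1
        T = 400
        t = np.arange(T) * tr
        wave = np.zeros(T)
        for f in (100, 250):
            wave += 2.0 * double_gamma(t - f * tr)
        run = make_run(wave[None, :], tr=tr, session_id="r")
        evs = [event(f + round(5 / tr), tr) for f in (100, 250)]
        curves = fir_estimate([run], evs * 3, min_events=5)
        single = fir_estimate([run], [evs[0]] * 5, min_events=5)
        i = np.argmax(curves[0].values)
        assert curves[0].values[i] == pytest.approx(
            single[0].values[np.argmax(single[0].values)], rel=0.05)

    def test_too_few_events_rejected(self, noise_run):
        with pytest.raises(ValueError, match="events"):
            fir_estimate([noise_run], [event(50)], min_events=5)


class TestFIRFeatures:
    def test_triangular_curve_geometry(self):
        values = np.zeros(11)
        values[3:8] = [0.0, 0.5, 1.0, 0.5, 0.0]
        curve = FIRCurve(values=values, lags_s=np.arange(11, dtype=float))
        peak, fwhm, delay = fir_features(curve)
        assert peak == 1.0
        assert fwhm == pytest.approx(2.0)
        assert delay == pytest.approx(5.0)

    def test_flat_curve_undefined(self):
        curve = FIRCurve(values=np.ones(9), lags_s=np.arange(9, dtype=float))
        peak, fwhm, delay = fir_features(curve)
        assert np.isnan(peak) and np.isnan(fwhm) and np.isnan(delay)

    def test_gaussian_fwhm_matches_analytic_relation(self):
        sigma = 3.0
        lags = np.arange(-20.0, 20.0, 0.5)
        curve = FIRCurve(values=np.exp(-0.5 * (lags / sigma) ** 2), lags_s=lags)
        _, fwhm, _ = fir_features(curve)
        assert fwhm == pytest.approx(FWHM_PER_SD * sigma, rel=0.05)

    def test_no_halfmax_crossing_flagged(self):
        # monotone rise: no left crossing below half-max inside window
        values = np.linspace(0.9, 1.0, 8)
        curve = FIRCurve(values=values, lags_s=np.arange(8, dtype=float))
        peak, fwhm, _ = fir_features(curve)
        assert np.isnan(fwhm)


class TestDispToFwhm:
    def test_printed_factor(self):
        assert disp_to_fwhm(1.0) == pytest.approx(2.3548, abs=1e-4)

    def test_linearity(self):
        assert disp_to_fwhm(0.5) == pytest.approx(2.3548 / 2, abs=1e-4)
        for x in (0.25, 1.75, 3.0):
            assert disp_to_fwhm(x) == pytest.approx(x * disp_to_fwhm(1.0))

    def test_matches_root_finding_on_unit_gaussian(self):
        half = lambda x: np.exp(-0.5 * x * x) - 0.5
        x_half = optimize.brentq(half, 0.0, 5.0, xtol=1e-14)
        assert disp_to_fwhm(1.0) == pytest.approx(2 * x_half, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            disp_to_fwhm(0.0)


class TestNormalizeAmplitudes:
    def test_single_gaussian_standardized(self, rng):
        x = rng.normal(3.0, 1.0, size=1000)
        z = normalize_amplitudes(x, seed=0)
        assert abs(z.mean()) <= 0.1
        assert abs(z.std() - 1.0) <= 0.1

    def test_contaminated_sample_maps_outliers_far(self, rng):
        x = np.concatenate([rng.normal(0, 1, 900), rng.normal(10, 1, 100)])
        z = normalize_amplitudes(x, seed=0)
        main = z[:900]
        out = z[900:]
        assert abs(main.mean()) < 0.3
        assert out.mean() == pytest.approx(10.0, abs=1.0)

    def test_affine_equivariance(self, rng):
        x = rng.normal(2.0, 3.0, size=500)
        z1 = normalize_amplitudes(x, seed=0)
        z2 = normalize_amplitudes(5.0 * x - 7.0, seed=0)
        np.testing.assert_allclose(z1, z2, atol=1e-4)

    def test_minimum_sample_size(self, rng):
        with pytest.raises(ValueError):
            normalize_amplitudes(rng.normal(size=10))


class TestHRFShape:
    def test_peak_time_near_mode(self):
        assert hrf_peak_time(5.0, 1.0) == pytest.approx(5.0, abs=0.2)

    def test_undershoot_negative_tail(self):
        t = np.linspace(0, 30, 301)
        h = double_gamma(t)
        assert h.min() < 0
        assert h[np.argmax(h)] == pytest.approx(1.0, abs=0.02)
        assert (h[t < 0] == 0).all() if (t < 0).any() else True
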