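import numpy as np
import pytest

from disuse.preprocess import (
    censor_frames,
    compute_snr_map,
    nuisance_regress,
    preprocess_run,
    smooth,
    temporal_filter,
)
from disuse.datamodel import StudyConfig

from conftest import make_run


class TestSNRMap:
    def test_constant_plus_unit_noise_tends_to_mean(self, rng):
        c = 7.0
        data = c + rng.standard_normal((20, 20000))
        snr = compute_snr_map(make_run(data))
        # variability -> 1 (variance denominator), so ratio -> c
        np.testing.assert_allclose(snr.value, c, rtol=0.05)

    def test_two_identical_runs_average_to_single(self, rng):
        data = rng.standard_normal((10, 100)) + 5
        r1, r2 = make_run(data, session_id="a"), make_run(data, session_id="b")
        np.testing.assert_allclose(compute_snr_map([r1, r2]).value,
                                   compute_snr_map(r1).value)

    def test_drop_map_maximum_is_zero(self, noise_run):
        assert compute_snr_map(noise_run).percent_drop.max() == 0.0

    def test_zero_variability_flagged_not_inf(self):
        data = np.vstack([np.ones(50), np.random.default_rng(0).random(50)])
        snr = compute_snr_map(make_run(data))
        assert np.isnan(snr.value[0])
        assert np.isfinite(snr.value[1])

    def test_sd_denominator_option(self, rng):
        data = 4.0 + 2.0 * rng.standard_normal((5, 20000))
        snr = compute_snr_map(make_run(data), denominator="sd")
        np.testing.assert_allclose(snr.value, 2.0, rtol=0.05)


class TestCensorFrames:
    def test_no_frames_removed_when_fd_zero(self, noise_run):
        censored, mask = censor_frames(noise_run, 0.1)
        assert mask.n_kept == noise_run.T
        np.testing.assert_array_equal(censored.data, noise_run.data)

    def test_exact_rule_on_small_trace(self, rng):
        run = make_run(rng.standard_normal((3, 4)).repeat(4, axis=1)[:, :4],
                       fd=[0.0, 0.05, 0.2, 0.05])
        censored, mask = censor_frames(run, 0.1, min_frames=3)
        np.testing.assert_array_equal(mask.keep, [True, True, False, True])
        assert censored.T == 3

    def test_retained_count_matches_counting_oracle(self, rng):
        fd = np.abs(rng.normal(0.08, 0.05, size=300))
        fd[0] = 0.0
        run = make_run(rng.standard_normal((4, 300)), fd=fd)
        _, mask = censor_frames(run, 0.1)
        assert mask.n_kept == int(np.sum(fd <= 0.1))

    def test_unusable_run_raises(self, rng):
        fd = np.full(50, 0.5)
        fd[0] = 0.0
        run = make_run(rng.standard_normal((4, 50)), fd=fd)
        with pytest.raises(ValueError, match="unusable"):
            censor_frames(run, 0.1)


class TestTemporalFilter:
    def test_out_of_band_sinusoid_attenuated(self):
        tr = 1.1
        t = np.arange(1200) * tr
        x = np.sin(2 * np.pi * 0.2 * t)
        run = make_run(np.tile(x, (2, 1)), tr=tr)
        out = temporal_filter(run, "bandpass", (0.005, 0.1))
        # steady-state amplitude well below 10% of input
        mid = slice(300, 900)
        assert np.abs(out.data[0, mid]).max() <= 0.1

    def test_dc_removed_by_bandpass(self, rng):
        x = rng.standard_normal((3, 400)) + 100.0
        out = temporal_filter(make_run(x), "bandpass", (0.005, 0.1))
        assert np.abs(out.data.mean(axis=1)).max() < 1e-8 * 100.0

    def test_in_band_sinusoid_idempotent_within_one_percent(self):
        tr = 1.1
        t = np.arange(2000) * tr
        x = np.sin(2 * np.pi * 0.03 * t)
        run = make_run(np.tile(x, (1, 1)), tr=tr)
        once = temporal_filter(run, "bandpass", (0.005, 0.1))
        twice = temporal_filter(once, "bandpass", (0.005, 0.1))
        mid = slice(400, 1600)
        a1 = np.abs(once.data[0, mid]).max()
        a2 = np.abs(twice.data[0, mid]).max()
        assert abs(a2 / a1 - 1) < 0.01

    def test_band_edge_beyond_nyquist_rejected(self, noise_run):
        with pytest.raises(ValueError):
            temporal_filter(noise_run, "bandpass", (0.005, 0.5))

    def test_highpass_only_keeps_fast_transient(self, rng):
        tr = 1.1
        x = rng.standard_normal((1, 400)) * 0.0
        x[0, 200:203] = 5.0
        run = make_run(x, tr=tr)
        hp = temporal_filter(run, "highpass_only", (0.005, 0.1))
        bp = temporal_filter(run, "bandpass", (0.005, 0.1))
        assert hp.data[0, 200:203].max() > bp.data[0, 200:203].max()


class TestNuisanceRegress:
    def test_data_equal_to_regressor_goes_to_zero(self, rng):
        T = 120
        motion = rng.standard_normal((T, 6))
        data = np.tile(motion[:, 2], (4, 1)) * 3.0
        run = make_run(data)
        out = nuisance_regress(run, motion_params=motion, include_global=False)
        assert np.abs(out.data).max() < 1e-8 * np.abs(data).max()

    def test_orthogonal_data_unchanged(self):
        T = 200
        t = np.arange(T)
        motion = np.column_stack([np.sin(2 * np.pi * k * t / T)
                                  for k in range(1, 7)])
        data = np.cos(2 * np.pi * 40 * t / T)[None, :]
        run = make_run(data)
        out = nuisance_regress(run, motion_params=motion, include_global=False)
        np.testing.assert_allclose(out.data, data, atol=1e-8)

    def test_removed_variance_matches_normal_equations(self, rng):
        T = 150
        motion = rng.standard_normal((T, 6))
        data = rng.standard_normal((8, T))
        run = make_run(data)
        out = nuisance_regress(run, motion_params=motion, include_global=False)
        X = np.column_stack([np.ones(T), motion])
        beta = np.linalg.solve(X.T @ X, X.T @ data.T)
        resid = data - (X @ beta).T
        np.testing.assert_allclose(out.data, resid, atol=1e-8)

    def test_idempotent(self, rng):
        T = 150
        motion = rng.standard_normal((T, 6))
        run = make_run(rng.standard_normal((5, T)))
        once = nuisance_regress(run, motion_params=motion)
        twice = nuisance_regress(once, motion_params=motion)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-8)

    def test_collinear_columns_dropped_with_warning(self, rng):
        T = 100
        m = rng.standard_normal((T, 3))
        motion = np.hstack([m, m])          # duplicated columns
        run = make_run(rng.standard_normal((4, T)))
        with pytest.warns(UserWarning, match="collinear"):
            nuisance_regress(run, motion_params=motion, include_global=False)


class TestSmooth:
    def test_delta_mass_conserved(self, tiny_space):
        x = np.zeros(tiny_space.n)
        x[tiny_space.indices("thalamus-left")[4]] = 1.0
        out = smooth(x, tiny_space)
        np.testing.assert_allclose(out.sum(), 1.0, atol=1e-6)

    def test_constant_map_unchanged(self, tiny_space):
        x = np.full(tiny_space.n, 3.3)
        np.testing.assert_allclose(smooth(x, tiny_space), x, atol=1e-10)

    def test_white_noise_variance_reduced(self, tiny_space, rng):
        x = rng.standard_normal((tiny_space.n, 50))
        out = smooth(x, tiny_space)
        assert out.var() < 0.9 * x.var()

    def test_never_mixes_structures(self, tiny_space):
        x = np.zeros(tiny_space.n)
        x[tiny_space.indices("thalamus-left")] = 10.0
        out = smooth(x, tiny_space)
        others = np.setdiff1d(np.arange(tiny_space.n),
                              tiny_space.indices("thalamus-left"))
        assert np.abs(out[others]).max() == 0.0


class TestPipelineOrder:
    def test_censor_interpolate_filter_recensor(self, tiny_space, rng):
        """The full chain equals the manual censor->interpolate->filter->
        re-censor sequence."""
        cfg = StudyConfig()
        T = 200
        fd = np.zeros(T)
        fd[[50, 51, 120]] = 0.5
        data = rng.standard_normal((tiny_space.n, T)) + 100
        run = make_run(data, fd=fd)
        got, mask = preprocess_run(run, tiny_space, cfg, do_smooth=False)
        filtered = temporal_filter(run, cfg.filter_mode, cfg.band,
                                   censor_mask=censor_frames(run, 0.1)[1])
        manual, _ = censor_frames(filtered, 0.1)
        manual = nuisance_regress(manual)
        np.testing.assert_allclose(got.data, manual.data, atol=1e-10)
        assert got.T == int(np.sum(fd <= 0.1))
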