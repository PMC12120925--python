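import numpy as np
import pytest

from disuse._utils import child_seed
from disuse.fc_change import phase_effect_size, seed_fc_map
from disuse.hrf import double_gamma
from disuse.simulate import (
    SimParams,
    decay_curve,
    make_space,
    make_truth,
    simulate_run,
    simulate_task_run,
)
from disuse.spatial_stats import moran_weights, morans_i
from disuse.preprocess import smooth


class TestMakeSpace:
    def test_construction_counts_and_symmetry(self, tiny_space, tiny_params):
        expect = (
            2 * np.prod(tiny_params.cortex_shape)
            + 2 * (np.prod(tiny_params.thalamus_shape)
                   + np.prod(tiny_params.putamen_shape)
                   + np.prod(tiny_params.pallidum_shape)
                   + np.prod(tiny_params.caudate_shape)
                   + np.prod(tiny_params.cerebellum_shape))
        )
        assert tiny_space.n == expect
        assert (tiny_space.adjacency != tiny_space.adjacency.T).nnz == 0

    def test_snr_lower_at_center_than_cortex(self, default_space):
        thal = default_space.indices("thalamus-left")
        ctx = default_space.indices("cortex-left")
        assert default_space.snr[thal].mean() < default_space.snr[ctx].mean()

    def test_interior_volume_voxel_has_degree_six(self, default_space):
        thal = default_space.indices("thalamus-left")
        deg = np.asarray(default_space.adjacency.sum(axis=1)).ravel()
        assert deg[thal].max() == 6

    def test_zero_size_structure_rejected(self):
        with pytest.raises(ValueError):
            make_space(SimParams(thalamus_shape=(0, 2, 2)))


class TestSimulateRun:
    def test_bit_reproducible_under_fixed_seed(self, tiny_space, tiny_params,
                                               tiny_truth):
        import dataclasses
        t1 = dataclasses.replace(tiny_truth, injected_pulses=[])
        t2 = dataclasses.replace(tiny_truth, injected_pulses=[])
        r1 = simulate_run(tiny_space, "cast-01", "cast", 1, tiny_params, t1, 9)
        r2 = simulate_run(tiny_space, "cast-01", "cast", 1, tiny_params, t2, 9)
        np.testing.assert_array_equal(r1.data, r2.data)
        assert t1.injected_pulses == t2.injected_pulses

    def test_noise_free_pulse_is_double_gamma(self, tiny_space, tiny_params):
        params = SimParams(**{**tiny_params.__dict__, "noise_sd": 0.0,
                              "motion_spike_rate": 0.0})
        truth = make_truth(tiny_space, params, 0)
        run = simulate_run(tiny_space, "cast-01", "cast", 1, params, truth,
                           seed=3, pulse_onsets=[40])
        roi = truth.rois["sm1ue-left"]
        series = run.data[roi].mean(axis=0)
        series = series - np.median(series)
        t = np.arange(len(series)) * params.tr_seconds
        kernel = double_gamma(t - 40 * params.tr_seconds)
        kernel = kernel / kernel.max()
        corr = np.corrcoef(series, kernel)[0, 1]
        assert corr > 0.999

    def test_onset_beyond_run_rejected(self, tiny_space, tiny_params,
                                       tiny_truth):
        with pytest.raises(ValueError, match="onset"):
            simulate_run(tiny_space, "cast-01", "cast", 1, tiny_params,
                         tiny_truth, seed=3,
                         pulse_onsets=[tiny_params.T + 5])

    def test_injected_count_matches_reconstruction_noise_free(
            self, tiny_space, tiny_params):
        params = SimParams(**{**tiny_params.__dict__, "noise_sd": 0.0,
                              "motion_spike_rate": 0.0})
        truth = make_truth(tiny_space, params, 0)
        onsets = [30, 80]
        run = simulate_run(tiny_space, "cast-01", "cast", 1, params, truth,
                           seed=3, pulse_onsets=onsets)
        assert len(truth.injected_pulses) == 2
        roi = truth.rois["sm1ue-left"]
        series = run.data[roi].mean(axis=0)
        base = np.median(series)
        # count local bumps: frames where the series rises above half the
        # kernel peak amplitude, merged into events
        above = series > base + 0.5 * (series.max() - base)
        n_events = int(np.sum(np.diff(above.astype(int)) == 1))
        assert n_events == len(onsets)

    def test_moran_i_monotone_in_smoothness(self, tiny_space, rng):
        idx, W = moran_weights(tiny_space, "cortex-left")
        i_vals = []
        noise = rng.standard_normal(tiny_space.n)
        for fwhm in (0.1, 4.0, 8.0):
            sm = smooth(noise, tiny_space, fwhm, fwhm)
            i_vals.append(morans_i(sm[idx], W))
        assert i_vals[0] < i_vals[1] < i_vals[2]


class TestEffectSizeGroundTruth:
    def test_null_effect_size_near_zero(self):
        """d=0 generator: mean empirical Cohen's d at the target region
        stays within +/-0.05 of zero over many session-set replicates."""
        params = SimParams(effect_d=0.0, pulse_rate_per_run=0.0,
                           cortex_shape=(8, 8), thalamus_shape=(3, 3, 3),
                           putamen_shape=(2, 2, 2), pallidum_shape=(2, 2, 3),
                           caudate_shape=(2, 3, 3), cerebellum_shape=(3, 3, 3),
                           T=150, fc_blob_size=20)
        space = make_space(params, 0)
        truth = make_truth(space, params, 0)
        ds = []
        for rep in range(120):
            maps = []
            for phase in ("pre", "cast"):
                for i in range(params.sessions_per_phase):
                    sid = f"{phase}-{i}"
                    run = simulate_run(space, sid, phase, 0, params, truth,
                                       seed=child_seed(rep * 13 + 1, sid))
                    maps.append(seed_fc_map(run, truth.rois["sm1ue-left"]))
            eff = phase_effect_size(maps, "cast", "pre")
            ds.append(np.nanmean(eff.d[truth.rois["fc-blob"]]))
        assert abs(np.mean(ds)) <= 0.05

    def test_calibrated_effect_size_recovered(self):
        """d=2.5 generator: empirical Cohen's d at the blob within +/-0.3
        of the target over 100 replicates."""
        params = SimParams()
        space = make_space(params, 0)
        truth = make_truth(space, params, 0)
        ds = []
        for rep in range(100):
            maps = []
            for phase in ("pre", "cast"):
                for i in range(params.sessions_per_phase):
                    sid = f"{phase}-{i}"
                    run = simulate_run(space, sid, phase, 0, params, truth,
                                       seed=child_seed(rep * 17 + 3, sid))
                    maps.append(seed_fc_map(run, truth.rois["sm1ue-left"]))
            eff = phase_effect_size(maps, "cast", "pre")
            ds.append(np.nanmean(eff.d[truth.rois["fc-blob"]]))
        assert abs(np.mean(ds) - params.effect_d) <= 0.3


class TestTaskRun:
    def test_zero_beta_equals_rest_run(self, tiny_space, tiny_params):
        import dataclasses
        truth = make_truth(tiny_space, tiny_params, 0)
        truth0 = dataclasses.replace(
            truth, task_betas={"right-hand": np.zeros(tiny_space.n)},
            injected_pulses=[])
        truth1 = dataclasses.replace(truth, injected_pulses=[])
        rest = simulate_run(tiny_space, "t", "pre", 0, tiny_params, truth1, 11)
        task = simulate_task_run(tiny_space, [("right-hand", 20.0, 15.0)],
                                 tiny_params, truth0, 11, session_id="t")
        np.testing.assert_allclose(task.data, rest.data)

    def test_noise_free_task_is_boxcar_convolved_hrf(self, tiny_space,
                                                     tiny_params):
        params = SimParams(**{**tiny_params.__dict__, "noise_sd": 0.0,
                              "motion_spike_rate": 0.0})
        truth = make_truth(tiny_space, params, 0)
        run = simulate_task_run(tiny_space, [("right-hand", 22.0, 16.5)],
                                params, truth, 7)
        voxel = truth.rois["sm1ue-left"][0]
        series = run.data[voxel] - np.median(run.data[voxel])
        t = np.arange(params.T) * params.tr_seconds
        box = ((t >= 22.0) & (t < 38.5)).astype(float)
        hrf = double_gamma(np.arange(0.0, 30.0, params.tr_seconds))
        expect = np.convolve(box, hrf)[:params.T]
        corr = np.corrcoef(series, expect)[0, 1]
        assert corr > 0.9999

    def test_overlapping_same_condition_blocks_rejected(self, tiny_space,
                                                        tiny_params,
                                                        tiny_truth):
        with pytest.raises(ValueError, match="overlap"):
            simulate_task_run(
                tiny_space,
                [("right-hand", 20.0, 15.0), ("right-hand", 25.0, 15.0)],
                tiny_params, tiny_truth, 7)


class TestDecayCurve:
    def test_continuity_at_cast_off(self):
        days = np.array([5.999, 6.001])
        y = decay_curve(days, 0.5, 0.8, 0.4, 0.1, t_cast=0.0, t_off=6.0)
        assert abs(y[0] - y[1]) < 1e-3

    def test_baseline_before_cast(self):
        y = decay_curve(np.array([-5.0, -1.0]), 0.5, 0.8, 0.4, 0.1,
                        t_cast=0.0, t_off=6.0)
        np.testing.assert_allclose(y, 0.1)
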