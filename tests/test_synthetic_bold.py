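"""Generator contracts: determinism, calibration, motion and ground truth."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from dtwconnect import (
    MotionTrace,
    RoiTimeseries,
    SimConfig,
    add_rician_noise,
    convolve_hrf,
    generate_cohort,
    generate_group_dataset,
    generate_motion_trace,
    generate_neural_timecourses,
    inject_global_signal,
    make_component_maps,
    pearson_fc_matrix,
    simulate_motion_corruption,
)
from dtwconnect.group_inference import edgewise_two_sample_t
from dtwconnect.pipeline import estimate_both
from dtwconnect.synthetic_bold import hrf_kernel


class TestNeuralTimecourses:
    def test_identity_coupling_gives_independent_regions(self):
        cfg = SimConfig(n_regions=6, n_volumes=4000, coupling=np.eye(6),
                        unique_event_rate_per_tr=0.0)
        neural = generate_neural_timecourses(cfg, subject_seed=3)
        r = np.corrcoef(neural)
        off = r[np.triu_indices(6, 1)]
        assert np.abs(off).max() < 0.08

    def test_duplicated_coupling_rows_give_identical_regions(self):
        coupling = np.eye(5)
        coupling[1] = coupling[0]
        cfg = SimConfig(n_regions=5, n_volumes=200, coupling=coupling,
                        unique_event_rate_per_tr=0.0)
        neural = generate_neural_timecourses(cfg, subject_seed=3)
        np.testing.assert_array_equal(neural[0], neural[1])

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_regions=5, n_volumes=100)
        a = generate_neural_timecourses(cfg, subject_seed=11)
        b = generate_neural_timecourses(cfg, subject_seed=11)
        np.testing.assert_array_equal(a, b)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_regions=0)


class TestHrf:
    def test_zero_input_zero_output(self):
        assert np.all(convolve_hrf(np.zeros(60), 1.0) == 0.0)

    def test_impulse_peaks_five_to_six_seconds(self):
        imp = np.zeros(60)
        imp[0] = 1.0
        out = convolve_hrf(imp, 1.0, 0.0)
        assert 5 <= np.argmax(out) <= 6

    def test_delay_shift_moves_peak(self):
        imp = np.zeros(80)
        imp[0] = 1.0
        a0 = np.argmax(convolve_hrf(imp, 1.0, 0.0))
        a2 = np.argmax(convolve_hrf(imp, 1.0, 2.0))
        assert abs((a2 - a0) - 2) <= 1

    def test_delay_changes_response_amplitude(self):
        """A later-peaking response is broader and shallower (area conserved)."""
        h0 = hrf_kernel(0.1, 0.0)
        h2 = hrf_kernel(0.1, 2.0)
        assert h2.max() < h0.max()
        assert h2.sum() * 0.1 == pytest.approx(h0.sum() * 0.1, rel=0.02)

    def test_invalid_delay_rejected(self):
        with pytest.raises(ValueError):
            hrf_kernel(1.0, -6.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            convolve_hrf(np.zeros(5), 1.0)


class TestRicianNoise:
    def test_vanishing_noise_limit(self, rng):
        signal = 100.0 + rng.normal(size=500)
        out = add_rician_noise(signal, cnr=1e9, seed=0)
        assert np.abs(out - signal).max() < 1e-3 * signal.std()

    def test_rayleigh_mean_on_zero_signal(self):
        """Zero in-phase signal: output is Rayleigh with mean sigma*sqrt(pi/2)."""
        out = add_rician_noise(np.zeros(200_000), cnr=1.0, seed=42, sigma=1.0)
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), abs=0.01)

    def test_deterministic_and_validated(self):
        x = np.linspace(0, 1, 50) + 100
        np.testing.assert_array_equal(
            add_rician_noise(x, 1.0, seed=5), add_rician_noise(x, 1.0, seed=5)
        )
        with pytest.raises(ValueError):
            add_rician_noise(x, cnr=0.0, seed=1)

    def test_cnr_calibration(self, rng):
        """Measured signal-SD/noise-SD within 10% of requested CNR."""
        signal = 100.0 + np.sin(np.linspace(0, 20 * np.pi, 180)) * 2.0
        for cnr in (0.65, 1.0, 2.0):
            reps = []
            for s in range(40):
                out = add_rician_noise(signal, cnr, seed=s)
                reps.append((out - signal).std())
            noise_sd = np.mean(reps)
            assert signal.std() / noise_sd == pytest.approx(cnr, rel=0.10)


class TestMotionTrace:
    def test_zero_bounds_give_zero_trace(self):
        cfg = SimConfig(max_translation_mm=0.0, max_rotation_deg=0.0)
        trace = generate_motion_trace(cfg, seed=1)
        assert np.all(trace.params == 0.0)

    def test_bounds_enforced(self):
        cfg = SimConfig()
        for seed in range(10):
            trace = generate_motion_trace(cfg, seed=seed)
            assert np.abs(trace.translations_mm).max() <= 0.02 + 1e-12
            assert np.abs(trace.rotations_deg).max() <= 5.0 + 1e-12
            assert trace.n_volumes == cfg.n_volumes

    def test_deterministic(self):
        cfg = SimConfig()
        np.testing.assert_array_equal(
            generate_motion_trace(cfg, seed=9).params,
            generate_motion_trace(cfg, seed=9).params,
        )


class TestMotionCorruption:
    def test_zero_trace_is_identity(self, rng):
        maps = make_component_maps(6, (16, 12), seed=0)
        tcs = rng.normal(size=(6, 40))
        zero = MotionTrace(np.zeros((40, 6)))
        voxels, ts = simulate_motion_corruption(maps, tcs, zero, (16, 12))
        np.testing.assert_allclose(voxels, maps.T @ tcs, atol=1e-12)
        masks = maps > 0.1 * maps.max(axis=1, keepdims=True)
        expected = (masks @ (maps.T @ tcs)) / masks.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(ts.values, expected.T, atol=1e-12)

    def test_single_voxel_translation_boundary_loss(self):
        """Shifting a uniform map one voxel off-grid loses a countable edge row."""
        nx, ny = 10, 8
        maps = np.ones((2, nx * ny))
        tcs = np.vstack([np.ones(3), np.zeros(3)])
        params = np.zeros((3, 6))
        params[:, 0] = 1.0 * 3.0  # one voxel at 3 mm/voxel, x direction
        trace = MotionTrace(params)
        voxels, ts = simulate_motion_corruption(
            maps, tcs, trace, (nx, ny), mm_per_voxel=3.0, spin_history_pct_per_mm=0.0
        )
        # brute-force pixel count: one x-row of ny voxels falls off the grid
        expected_mean = (nx - 1) * ny / (nx * ny)
        np.testing.assert_allclose(ts.values[:, 0], expected_mean, atol=1e-10)

    def test_deterministic(self, rng):
        maps = make_component_maps(4, (16, 12), seed=1)
        tcs = rng.normal(size=(4, 20))
        cfg = SimConfig(n_volumes=20)
        trace = generate_motion_trace(cfg, seed=2)
        a = simulate_motion_corruption(maps, tcs, trace, (16, 12))[0]
        b = simulate_motion_corruption(maps, tcs, trace, (16, 12))[0]
        np.testing.assert_array_equal(a, b)

    def test_grid_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_motion_corruption(
                np.ones((1, 6)), np.ones((1, 3)), MotionTrace(np.zeros((3, 6))), (3, 2)
            )


class TestGlobalSignal:
    def test_zero_amplitude_is_identity(self, random_timeseries):
        out, g = inject_global_signal(random_timeseries, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, random_timeseries.values)
        assert np.all(g == 0)

    def test_dominant_global_drives_fc_to_one(self, random_timeseries):
        out, _ = inject_global_signal(random_timeseries, 50.0, seed=1)
        fc = pearson_fc_matrix(out)
        iu = np.triu_indices(out.n_regions, 1)
        assert fc.values[iu].mean() > 2.0  # Fisher z of r ~ 1

    def test_regional_lags_attenuate_pearson_not_dtw_ordering(self, rng):
        """Lagged copies of a strong global lower Pearson edges vs the
        zero-lag control while the DTW distance stays near zero."""
        base = RoiTimeseries(100 + rng.normal(0, 0.1, (120, 4)), tr_seconds=2.0)
        lags = np.array([0.0, 4.0, 8.0, 12.0])
        zero_lag, _ = inject_global_signal(base, 10.0, seed=3)
        lagged, _ = inject_global_signal(base, 10.0, seed=3, region_lags_seconds=lags)
        iu = np.triu_indices(4, 1)
        r_zero = pearson_fc_matrix(zero_lag).values[iu].mean()
        r_lag = pearson_fc_matrix(lagged).values[iu].mean()
        assert r_lag < r_zero
        from dtwconnect import dtw_distance

        d = dtw_distance(lagged.values[:, 0], lagged.values[:, 1], 50)
        sync = np.abs(lagged.values[:, 0] - lagged.values[:, 1]).sum()
        assert d < 0.35 * sync  # warping recovers most of the lagged alignment


class TestCohorts:
    def test_cohort_bit_identical_given_seed(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        for sa, sb in zip(a.scans, b.scans):
            np.testing.assert_array_equal(sa.timeseries.values, sb.timeseries.values)
            np.testing.assert_array_equal(sa.motion.params, sb.motion.params)
            np.testing.assert_array_equal(sa.noise_voxels, sb.noise_voxels)
        np.testing.assert_array_equal(a.coupling, b.coupling)

    def test_cohort_shapes_and_ground_truth(self, small_config):
        cohort = generate_cohort(small_config)
        assert len(cohort.scans) == small_config.n_subjects
        for scan in cohort.scans:
            assert scan.timeseries.values.shape == (120, 8)
            assert scan.motion.n_volumes == 120
        assert cohort.region_lags_seconds.shape == (8,)
        assert cohort.hrf_delays_seconds.shape == (8,)
        assert cohort.region_amplitudes.shape == (8,)

    def test_group_effect_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_regions=5, group_effects=(((0, 9), "coupling-delta", 1.0),))
        with pytest.raises(ValueError):
            SimConfig(n_regions=5, group_effects=(((0, 1), "bogus", 1.0),))

    def test_null_cohort_pvalues_uniform(self):
        """With no group effects, edgewise t-test p-values pass a KS test
        against the uniform distribution (m = 300 edges)."""
        cfg = SimConfig(n_subjects=20, n_regions=25, n_volumes=180, seed=31)
        cohort = generate_group_dataset(cfg)
        from dtwconnect.fc_core import DtwConfig

        by_group = {"A": [], "B": []}
        for scan in cohort.scans:
            by_group[scan.group].append(
                estimate_both(scan.timeseries, DtwConfig())["pearson"]
            )
        res = edgewise_two_sample_t(by_group["A"], by_group["B"])
        ks = stats.kstest(res.valid_pvalues(), "uniform")
        assert ks.pvalue > 0.01

    def test_coupling_delta_dominates_t_statistics(self):
        """An injected +0.8 coupling change is the top-|t| edge in >= 90%
        of replicate cohorts."""
        hits = 0
        reps = 50
        for rep in range(reps):
            cfg = SimConfig(
                n_subjects=40, n_regions=10, n_volumes=120, seed=6000 + rep,
                group_effects=(((0, 5), "coupling-delta", 0.8),),
            )
            cohort = generate_group_dataset(cfg)
            by_group = {"A": [], "B": []}
            for scan in cohort.scans:
                by_group[scan.group].append(
                    pearson_fc_matrix(scan.timeseries, scan.subject_id)
                )
            res = edgewise_two_sample_t(by_group["A"], by_group["B"])
            iu = np.triu_indices(10, 1)
            target = [k for k, (i, j) in enumerate(zip(*iu)) if (i, j) == (0, 5)][0]
            hits += np.nanargmax(np.abs(res.statistic)) == target
        assert hits >= 0.9 * reps


class TestMotionMonotonicity:
    def test_pattern_similarity_non_increasing_in_amplitude(self):
        """Averaged over seeds, FC-pattern similarity between motion-free
        and motion-corrupted runs does not increase with trace amplitude."""
        from dtwconnect.comparison_metrics import fc_pattern_similarity
        from dtwconnect.synthetic_bold import (
            BASELINE, _draw_region_params, generate_subject_fluctuations)

        grid = (20, 15)
        base = SimConfig(n_regions=10, n_volumes=120, seed=0, grid_shape=grid)
        maps = make_component_maps(10, grid, seed=1)
        masks = maps > 0.1 * maps.max(axis=1, keepdims=True)
        sizes = masks.sum(axis=1, keepdims=True)
        zero = MotionTrace(np.zeros((120, 6)))
        scales = (0.5, 1.0, 2.0)
        sims = {sc: [] for sc in scales}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lags, delays, amps = _draw_region_params(base, rng)
            fluct = generate_subject_fluctuations(
                base, 900 + seed, base.resolved_coupling(), lags, delays, amps)
            runs = {}
            for sc in (0.0,) + scales:
                cfg = replace(base,
                              max_translation_mm=0.02 * sc,
                              max_rotation_deg=5.0 * sc)
                trace = zero if sc == 0.0 else generate_motion_trace(cfg, seed=77 + seed)
                vox, _ = simulate_motion_corruption(
                    maps, fluct, trace, grid, baseline=BASELINE,
                    spin_history_pct_per_mm=base.spin_history_pct_per_mm)
                noisy = add_rician_noise(vox, 1.3, seed=500 + seed, sigma=1.0 / 1.3)
                roi = (masks @ noisy) / sizes
                from dtwconnect.denoise import percent_signal_change

                runs[sc] = pearson_fc_matrix(
                    percent_signal_change(RoiTimeseries(roi.T, 2.0)))
            for sc in scales:
                sims[sc].append(fc_pattern_similarity(runs[0.0], runs[sc]))
        means = [np.mean(sims[sc]) for sc in scales]
        assert means[0] >= means[1] - 1e-9 >= means[2] - 2e-9
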