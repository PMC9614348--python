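"""Ground-truth consistency and reproducibility of the synthetic generators."""

import numpy as np
import pytest
from scipy.stats import binom

from fusionscope.flic_optics import FlicOpticsParams
from fusionscope.synthgen import (
    BindingSimConfig,
    BlmSimConfig,
    FlicSimConfig,
    TirfSimConfig,
    simulate_binding_series,
    simulate_current_trace,
    simulate_flic_sets,
    simulate_tirf_movie,
)

SMALL = dict(n_frames=400, image_shape=(64, 64), end_margin=60)


class TestTirfGenerator:
    def test_zero_docking_rate_gives_pure_background(self):
        cfg = TirfSimConfig(docking_rate=0.0, background_sd=0.0, seed=0, **SMALL)
        movie, truth = simulate_tirf_movie(cfg)
        assert truth == []
        np.testing.assert_allclose(movie.data, cfg.background_mean)

    def test_forced_fusion_spike_equals_gain_times_plateau(self):
        cfg = TirfSimConfig(
            fusion_probability=1.0, background_sd=0.0, background_mean=0.0,
            docking_rate=6 / 400, seed=1, **SMALL,
        )
        movie, truth = simulate_tirf_movie(cfg)
        assert truth and all(v.fused for v in truth)
        for v in truth:
            series = movie.data[:, v.row, v.col]
            plateau = series[v.dock_frame]
            assert series.max() == pytest.approx(cfg.spike_gain * plateau, rel=1e-5)
            assert series[v.fusion_frame] == series.max()

    def test_docking_only_trace_holds_plateau(self):
        cfg = TirfSimConfig(
            fusion_probability=0.0, background_sd=0.0, background_mean=0.0,
            docking_rate=6 / 400, seed=2, **SMALL,
        )
        movie, truth = simulate_tirf_movie(cfg)
        for v in truth:
            series = movie.data[:, v.row, v.col]
            np.testing.assert_allclose(series[v.dock_frame :], v.plateau, rtol=1e-6)

    def test_fused_fraction_within_binomial_interval(self):
        # expected ~200 docking events at the control fusion probability
        cfg = TirfSimConfig(docking_rate=200 / 3000, fusion_probability=0.34, seed=1)
        _, truth = simulate_tirf_movie(cfg)
        n = len(truth)
        k = sum(v.fused for v in truth)
        lo, hi = binom.ppf([0.025, 0.975], n, 0.34)
        assert lo <= k <= hi

    def test_fusion_delays_within_cutoff_and_mostly_fast(self):
        cfg = TirfSimConfig(fusion_probability=1.0, docking_rate=250 / 3000, seed=3)
        _, truth = simulate_tirf_movie(cfg)
        delays = np.array(
            [(v.fusion_frame - v.dock_frame) * cfg.frame_interval for v in truth]
        )
        assert np.all(delays <= cfg.fusion_delay_max + 1e-9)
        # ~65% of fusing vesicles fuse within 250 ms
        assert np.mean(delays <= 0.25) == pytest.approx(0.65, abs=0.08)

    def test_seed_reproducibility(self):
        cfg = TirfSimConfig(seed=7, **SMALL, docking_rate=10 / 400)
        m1, t1 = simulate_tirf_movie(cfg)
        m2, t2 = simulate_tirf_movie(cfg)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert [(v.dock_frame, v.fusion_frame) for v in t1] == [
            (v.dock_frame, v.fusion_frame) for v in t2
        ]

    def test_poisson_event_counts(self):
        # mean docked count over many seeds within 3 SE of rate * n_frames
        rate, n_frames = 8 / 200, 200
        counts = []
        for seed in range(200):
            cfg = TirfSimConfig(
                n_frames=n_frames, image_shape=(64, 64), docking_rate=rate,
                background_sd=0.0, end_margin=50, seed=seed,
            )
            _, truth = simulate_tirf_movie(cfg)
            counts.append(len(truth))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - rate * n_frames) <= 3 * se

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            TirfSimConfig(image_shape=(4, 4))


class TestBindingGenerator:
    def test_no_fusion_saturation(self):
        cfg = BindingSimConfig(alpha=0.0, beta=5.0, noise_sd=0.0,
                               n_liposomes_saturation=100, i_liposome=2.0,
                               baseline=10.0, duration=3000.0, seed=0)
        tc, truth = simulate_binding_series(cfg)
        assert truth["saturation_intensity"] == pytest.approx(200.0)
        assert tc.mean_intensity[-1] == pytest.approx(10.0 + 200.0, rel=1e-9)

    def test_all_fused_saturation_doubles(self):
        cfg = BindingSimConfig(alpha=1.0, beta=2.0, noise_sd=0.0,
                               n_liposomes_saturation=100, i_liposome=1.0,
                               baseline=0.0, duration=3000.0, seed=0)
        tc, truth = simulate_binding_series(cfg)
        assert truth["saturation_intensity"] == pytest.approx(200.0)

    def test_half_fused_saturation(self):
        cfg = BindingSimConfig(alpha=0.5, beta=2.0, noise_sd=0.0,
                               n_liposomes_saturation=100, i_liposome=1.0,
                               baseline=0.0, seed=0)
        _, truth = simulate_binding_series(cfg)
        assert truth["saturation_intensity"] == pytest.approx(150.0)

    def test_baseline_images_flagged(self):
        tc, _ = simulate_binding_series(BindingSimConfig(seed=0))
        assert tc.is_baseline.sum() == 3
        assert not tc.is_baseline[3:].any()


class TestFlicGenerator:
    def test_noiseless_sets_are_identical(self):
        cfg = FlicSimConfig(noise_fraction=0.0, n_sets=2, seed=0)
        a, b = simulate_flic_sets(cfg, FlicOpticsParams())
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_zero_scale_gives_background(self):
        cfg = FlicSimConfig(scale=0.0, noise_fraction=0.0, n_sets=1, seed=0)
        (m,) = simulate_flic_sets(cfg, FlicOpticsParams())
        np.testing.assert_allclose(m.intensities, cfg.background)

    def test_sixteen_terraces_required(self):
        with pytest.raises(ValueError):
            FlicSimConfig(oxide_thicknesses=(10.0, 20.0))


class TestBlmGenerator:
    def test_zero_rate_pure_noise(self):
        trace, truth = simulate_current_trace(BlmSimConfig(event_rate=0.0, seed=0))
        assert truth.size == 0
        assert trace.current.std() < 4 * 2.5

    def test_seed_reproducibility_bitwise(self):
        cfg = BlmSimConfig(seed=5)
        t1, e1 = simulate_current_trace(cfg)
        t2, e2 = simulate_current_trace(cfg)
        np.testing.assert_array_equal(t1.current, t2.current)
        np.testing.assert_array_equal(e1, e2)

    def test_fixed_event_times_inserted_exactly(self):
        times = (10.0, 50.0, 100.0)
        cfg = BlmSimConfig(event_times=times, noise_sd=0.0, seed=0)
        trace, truth = simulate_current_trace(cfg)
        np.testing.assert_array_equal(truth, times)
        dt = trace.sample_interval
        for t0 in times:
            i0 = int(np.ceil(t0 / dt - 1e-12))
            step = trace.current[i0] - trace.current[i0 - 1]
            assert step > 5.0

    def test_event_count_mean_matches_rate(self):
        counts = [
            simulate_current_trace(
                BlmSimConfig(seed=s, event_rate=12.0, sample_rate=50.0)
            )[1].size
            for s in range(300)
        ]
        mean = np.mean(counts)
        expected = 12.0 * 210.0 / 60.0
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) <= 3 * se
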