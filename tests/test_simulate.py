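"""Statistical and limiting-case checks of the synthetic-microscopy generators."""

import numpy as np
import pytest

from pmspt.simulate import (ConfocalSimParams, FlimSimParams, TirfSimParams,
                            render_spots, simulate_confocal_stack,
                            simulate_flim, simulate_tirf_movie)


class TestTirfSimulator:
    def test_zero_diffusion_particle_is_stationary(self):
        p = TirfSimParams(diffusion_um2_s=0.0, dwell_mean_s=np.inf,
                          n_initial=1, birth_rate_per_frame=0.0,
                          n_frames=20, seed=3)
        _, truth = simulate_tirf_movie(p, render=False)
        pos = truth.positions
        assert pos["id"].nunique() == 1
        assert len(pos) == 20
        assert np.ptp(pos["x_um"]) == 0.0
        assert np.ptp(pos["y_um"]) == 0.0

    def test_dark_spots_leave_only_camera_noise(self):
        # read-noise-dominated camera: with no spot photons, no pixel of
        # 100 frames should exceed background + 6 read-noise SDs
        p = TirfSimParams(photons_per_spot=0.0, background_photons=1.0,
                          read_noise_sd=10.0, n_frames=100, n_initial=50,
                          birth_rate_per_frame=1.0, seed=4)
        stack, _ = simulate_tirf_movie(p)
        assert stack.frames.max() <= 1.0 + 6 * 10.0

    def test_brownian_step_variance_matches_2dt(self):
        d, dt = 2e-3, 0.15
        p = TirfSimParams(field_size_px=(256, 256), diffusion_um2_s=d,
                          dwell_mean_s=np.inf, n_initial=60,
                          birth_rate_per_frame=0.0, n_frames=30, seed=5)
        _, truth = simulate_tirf_movie(p, render=False)
        steps = []
        for _, g in truth.positions.groupby("id"):
            steps.extend(np.diff(g["x_um"].to_numpy()))
            steps.extend(np.diff(g["y_um"].to_numpy()))
        steps = np.asarray(steps)
        assert len(steps) >= 500
        assert np.var(steps) == pytest.approx(2 * d * dt, rel=0.20)

    def test_dwell_times_are_exponential_with_requested_mean(self):
        p = TirfSimParams(dwell_mean_s=2.0, birth_rate_per_frame=3.0,
                          n_frames=2000, seed=6)
        _, truth = simulate_tirf_movie(p, render=False)
        born = truth.particles[~truth.particles["start_censored"]]
        lifetimes = born.loc[~born["boundary_exit"], "lifetime_s"]
        assert len(lifetimes) >= 1000
        assert lifetimes.mean() == pytest.approx(2.0, rel=0.05)

    def test_rendered_spots_conserve_photons(self):
        img = render_spots((64, 64), [20.3, 40.7], [30.1, 10.9], 500.0, 1.2)
        assert img.sum() == pytest.approx(2 * 500.0, rel=1e-6)

    def test_identical_seeds_are_bit_identical(self):
        p1 = TirfSimParams(n_frames=5, n_initial=10, seed=11)
        p2 = TirfSimParams(n_frames=5, n_initial=10, seed=11)
        s1, t1 = simulate_tirf_movie(p1)
        s2, t2 = simulate_tirf_movie(p2)
        assert np.array_equal(s1.frames, s2.frames)
        assert t1.positions.equals(t2.positions)
        s3, _ = simulate_tirf_movie(TirfSimParams(n_frames=5, n_initial=10,
                                                  seed=12))
        assert not np.array_equal(s1.frames, s3.frames)

    @pytest.mark.parametrize("field,value", [
        ("n_frames", 1), ("frame_interval_s", 0.0), ("psf_sigma_px", -1.0),
        ("photons_per_spot", -5.0), ("dwell_mean_s", 0.0),
    ])
    def test_invalid_parameters_name_the_field(self, field, value):
        p = TirfSimParams(**{field: value})
        with pytest.raises(ValueError, match=field):
            p.validate()


class TestConfocalSimulator:
    def test_pure_membrane_signal_stays_on_the_shell(self):
        p = ConfocalSimParams(internal_fraction=0.0, background_photons=0.0,
                              read_noise_sd=0.0, seed=1)
        stack, truth = simulate_confocal_stack(p)
        from scipy.ndimage import binary_dilation
        near_pm = binary_dilation(truth.pm_mask, iterations=3)
        total = stack.slices.sum()
        on_shell = stack.slices[:, near_pm].sum()
        assert on_shell / total > 0.99

    def test_fully_internalized_signal_stays_in_the_cytoplasm(self):
        p = ConfocalSimParams(internal_fraction=1.0, background_photons=0.0,
                              read_noise_sd=0.0, seed=2)
        stack, truth = simulate_confocal_stack(p)
        total = stack.slices.sum()
        inside = stack.slices[:, truth.cyto_mask].sum()
        assert inside / total > 0.99

    def test_volume_intensity_ratio_matches_set_fraction(self):
        # direct sum over the generated volume at the 8 h treatment level
        p = ConfocalSimParams(internal_fraction=0.23, background_photons=0.0,
                              read_noise_sd=0.0, seed=3)
        stack, truth = simulate_confocal_stack(p)
        assert truth.internal_fraction_true == pytest.approx(0.23, abs=1e-9)
        h, w = p.shape_px
        yy, xx = np.mgrid[0:h, 0:w]
        dist = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
        r = p.cell_radius_um / p.pixel_size_um
        cyto = dist <= r - 5
        cell = dist <= r + 4
        ratio = stack.slices[:, cyto].sum() / stack.slices[:, cell].sum()
        assert ratio == pytest.approx(0.23, abs=0.01)

    def test_fraction_outside_unit_interval_is_rejected(self):
        with pytest.raises(ValueError, match="internal_fraction"):
            ConfocalSimParams(internal_fraction=1.2).validate()


class TestFlimSimulator:
    def test_truncated_decay_mean_matches_closed_form(self):
        tau, window = 2.53, 25.0
        p = FlimSimParams(lifetime_map_ns=np.full((4, 4), tau),
                          photons_per_pixel=1e5, window_ns=window,
                          n_bins=500, seed=4)
        data = simulate_flim(p)
        centers = data.bin_centers_ns
        mean = (data.counts.sum(axis=(0, 1)) * centers).sum() / data.counts.sum()
        expected = tau - window / np.expm1(window / tau)
        assert mean == pytest.approx(expected, rel=0.01)

    def test_no_photons_gives_empty_histograms(self):
        p = FlimSimParams(photons_per_pixel=0.0, seed=5)
        data = simulate_flim(p)
        assert data.counts.sum() == 0

    def test_two_region_map_orders_empirical_means(self):
        tau_map = np.full((8, 8), 2.1)
        tau_map[:, 4:] = 2.7
        p = FlimSimParams(lifetime_map_ns=tau_map, photons_per_pixel=5e3,
                          seed=6)
        data = simulate_flim(p)
        centers = data.bin_centers_ns
        def region_mean(sel):
            c = data.counts[:, sel, :].sum(axis=(0, 1))
            return (c * centers).sum() / c.sum()
        assert region_mean(slice(0, 4)) < region_mean(slice(4, 8))

    def test_window_must_exceed_lifetimes(self):
        with pytest.raises(ValueError, match="window_ns"):
            FlimSimParams(lifetime_map_ns=np.full((2, 2), 3.0),
                          window_ns=2.5).validate()
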