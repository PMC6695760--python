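"""Lifetime fitting, map rendering and FRET efficiency."""

import math

import numpy as np
import pytest

from pmspt.errors import RefusalError
from pmspt.flim import (FLIMData, fit_lifetime_map, fit_pixel_lifetime,
                        fret_efficiency, fret_from_rois, naive_mean_lifetime,
                        render_lifetime_map, roi_lifetime, truncated_exp_mean)
from pmspt.simulate import FlimSimParams, simulate_flim


def _decay_histogram(tau, window=25.0, n_bins=250, photons=100_000, seed=0):
    params = FlimSimParams(lifetime_map_ns=np.full((1, 1), tau),
                           photons_per_pixel=photons, window_ns=window,
                           n_bins=n_bins, seed=seed)
    return simulate_flim(params)


class TestPixelLifetime:
    def test_truncated_mean_closed_form(self):
        assert truncated_exp_mean(2.53, 25.0) == pytest.approx(
            2.53 - 25.0 / math.expm1(25.0 / 2.53))
        # with a huge window the mean approaches tau itself
        assert truncated_exp_mean(2.0, 1e5) == pytest.approx(2.0)

    def test_bright_pixel_recovered_within_one_percent(self):
        data = _decay_histogram(2.5)
        fit = fit_pixel_lifetime(data.counts[0, 0], data.bin_width_ns,
                                 data.window_ns)
        assert fit.ok
        assert fit.tau_ns == pytest.approx(2.5, rel=0.01)

    def test_empty_histogram_flagged_unfit(self):
        fit = fit_pixel_lifetime(np.zeros(250), 0.1, 25.0)
        assert not fit.ok
        assert fit.quality == "low_photons"

    def test_everything_in_first_bin_is_degenerate(self):
        hist = np.zeros(250)
        hist[0] = 1000
        fit = fit_pixel_lifetime(hist, 0.1, 25.0)
        assert fit.quality == "degenerate"
        assert fit.tau_ns <= 0.1

    def test_mle_removes_truncation_bias_of_naive_mean(self):
        # short window: the raw mean-arrival estimate is badly biased low
        data = _decay_histogram(2.5, window=8.0, n_bins=160, seed=3)
        hist = data.counts[0, 0]
        naive = naive_mean_lifetime(hist, data.bin_width_ns)
        mle = fit_pixel_lifetime(hist, data.bin_width_ns, data.window_ns)
        assert naive < 2.5 * 0.9
        assert mle.tau_ns == pytest.approx(2.5, rel=0.02)

    def test_lsq_fallback_agrees_on_clean_decay(self):
        data = _decay_histogram(2.5, seed=4)
        fit = fit_pixel_lifetime(data.counts[0, 0], data.bin_width_ns,
                                 data.window_ns, method="lsq")
        assert fit.tau_ns == pytest.approx(2.5, rel=0.05)


class TestMapAndRoi:
    def test_uniform_map_roi_average(self):
        params = FlimSimParams(lifetime_map_ns=np.full((8, 8), 2.53),
                               photons_per_pixel=2e4, seed=5)
        lt = fit_lifetime_map(simulate_flim(params))
        mean, sd, n = roi_lifetime(lt, np.ones((8, 8), bool))
        assert n == 64
        assert mean == pytest.approx(2.53, rel=0.01)
        assert sd < 0.05

    def test_half_and_half_map_averages_midway(self):
        tau = np.full((6, 6), 2.1)
        tau[:, 3:] = 2.7
        params = FlimSimParams(lifetime_map_ns=tau, photons_per_pixel=2e4,
                               seed=6)
        lt = fit_lifetime_map(simulate_flim(params))
        mean, _, _ = roi_lifetime(lt, np.ones((6, 6), bool))
        assert mean == pytest.approx(2.4, abs=0.02)

    def test_roi_without_fit_pixels_refused(self):
        params = FlimSimParams(lifetime_map_ns=np.full((4, 4), 2.5),
                               photons_per_pixel=0.0, seed=7)
        lt = fit_lifetime_map(simulate_flim(params))
        assert not lt.ok.any()
        with pytest.raises(RefusalError):
            roi_lifetime(lt, np.ones((4, 4), bool))

    def test_render_uses_fixed_absolute_scale(self):
        import matplotlib
        cm = matplotlib.colormaps["jet"]
        def render_uniform(tau):
            from pmspt.flim import LifetimeMap
            lt = LifetimeMap(np.full((3, 3), tau), np.full((3, 3), 1000),
                             np.ones((3, 3), bool))
            return render_lifetime_map(lt)
        navy = np.array(cm(0.0)[:3]) * 255
        red = np.array(cm(1.0)[:3]) * 255
        assert np.allclose(render_uniform(2.1)[0, 0], navy.astype(np.uint8))
        assert np.allclose(render_uniform(2.7)[0, 0], red.astype(np.uint8))
        # the scale is absolute: same tau -> same color, clamped outside
        assert np.array_equal(render_uniform(2.4), render_uniform(2.4))
        assert np.array_equal(render_uniform(3.5), render_uniform(2.7))
        from pmspt.flim import LifetimeMap
        lt = LifetimeMap(np.full((2, 2), np.nan), np.zeros((2, 2)),
                         np.zeros((2, 2), bool))
        assert render_lifetime_map(lt).max() == 0  # unfit pixels black

    def test_counts_window_consistency_enforced(self):
        with pytest.raises(ValueError, match="window_ns"):
            FLIMData(np.zeros((2, 2, 10)), bin_width_ns=0.1, window_ns=25.0)


class TestFretEfficiency:
    def test_equal_lifetimes_give_zero(self):
        assert fret_efficiency(2.53, 2.53) == 0.0

    def test_printed_lifetimes_give_six_point_seven_two(self):
        assert fret_efficiency(2.53, 2.36) == pytest.approx(
            (1 - 2.36 / 2.53) * 100.0)

    def test_half_lifetime_gives_fifty_percent(self):
        assert fret_efficiency(3.0, 1.5) == pytest.approx(50.0)

    def test_longer_da_lifetime_reported_negative(self):
        assert fret_efficiency(2.36, 2.50) < 0.0

    def test_nonpositive_lifetime_refused(self):
        with pytest.raises(RefusalError):
            fret_efficiency(0.0, 2.0)

    def test_strictly_decreasing_in_da_lifetime(self):
        taus = np.linspace(1.5, 2.53, 20)
        effs = [fret_efficiency(2.53, t) for t in taus]
        assert np.all(np.diff(effs) < 0)

    def test_per_roi_and_pooled_averaging_both_reported(self):
        out = fret_from_rois([2.5, 2.56], [2.3, 2.42])
        assert out["pooled_pct"] == pytest.approx(
            (1 - 2.36 / 2.53) * 100, abs=0.5)
        assert abs(out["per_roi_pct"] - out["pooled_pct"]) < 1.0
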