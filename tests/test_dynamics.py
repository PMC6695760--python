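"""MSD, diffusion fitting, motion range and population-peak checks.

Expected values are either closed forms of simple geometry or come from
the independent brute-force oracle in conftest.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import msd_bruteforce, random_trajectory
from pmspt.dynamics import (MSDCurve, compute_msd, fit_diffusion,
                            fit_population_peak, motion_range)
from pmspt.errors import FitError, RefusalError
from pmspt.tracking import Trajectory


def _traj(xs, ys, frames=None):
    n = len(xs)
    return Trajectory(0, frames if frames is not None else np.arange(n),
                      xs, ys, np.ones(n))


class TestMSD:
    def test_collinear_unit_steps(self):
        t = _traj([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        msd = compute_msd(t, 2, 0.15)
        assert msd.msd_um2[0] == 0.0
        assert msd.msd_um2[1] == pytest.approx(1.0)
        assert msd.msd_um2[2] == pytest.approx(4.0)
        assert msd.lag_times_s[1] == pytest.approx(0.15)

    def test_stationary_trajectory_has_zero_msd(self):
        t = _traj([1.0] * 8, [2.0] * 8)
        msd = compute_msd(t, 5, 0.15)
        assert np.all(msd.msd_um2 == 0.0)

    def test_pair_counts_decrease_with_lag(self):
        t = _traj(np.arange(10.0), np.zeros(10))
        msd = compute_msd(t, 9, 0.15)
        assert np.all(np.diff(msd.n_pairs) < 0)

    def test_max_lag_truncated_to_span(self):
        t = _traj([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        msd = compute_msd(t, 50, 0.15)
        assert len(msd.msd_um2) == 3  # lags 0..2

    def test_pairs_spanning_gaps_are_skipped_by_default(self):
        t = _traj([0.0, 1.0, 3.0], [0.0, 0.0, 0.0], frames=[0, 1, 3])
        msd = compute_msd(t, 3, 0.15)
        assert msd.n_pairs[1] == 1          # only (0,1): (1,3) spans frame 2
        assert msd.n_pairs[2] == 0
        spanning = compute_msd(t, 3, 0.15, gap_policy="span")
        assert spanning.n_pairs[2] == 1     # (1,3) allowed when spanning

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(min_value=2, max_value=20), st.integers(0, 10 ** 6))
    def test_matches_bruteforce_oracle(self, n_points, seed):
        rng = np.random.default_rng(seed)
        traj = random_trajectory(rng, n_points, with_gaps=True)
        max_lag = int(traj.frames[-1] - traj.frames[0])
        msd = compute_msd(traj, max_lag, 0.15)
        for (lag_t, val, n), got_val, got_n in zip(
                msd_bruteforce(traj, max_lag, 0.15),
                msd.msd_um2[1:], msd.n_pairs[1:]):
            assert got_n == n
            assert got_val == pytest.approx(val, abs=1e-12)


class TestDiffusionFit:
    def test_exact_line_recovers_d_and_unit_r2(self):
        d = 2e-3
        lags = np.arange(5) * 0.15
        msd = MSDCurve(lags, 4 * d * lags, np.array([10, 9, 8, 7, 6]))
        est = fit_diffusion(msd, n_lags=4)
        assert est.D_um2_s == pytest.approx(d, rel=1e-12)
        assert est.intercept_um2 == pytest.approx(0.0, abs=1e-15)
        assert est.r2 == pytest.approx(1.0)
        assert not est.clamped

    def test_offset_shifts_intercept_not_slope(self):
        d = 2e-3
        lags = np.arange(5) * 0.15
        msd = MSDCurve(lags, 4 * d * lags + 0.01, np.array([10, 9, 8, 7, 6]))
        est = fit_diffusion(msd, n_lags=4)
        assert est.D_um2_s == pytest.approx(d, rel=1e-9)
        assert est.intercept_um2 == pytest.approx(0.01, rel=1e-9)

    def test_negative_slope_clamps_to_zero_with_flag(self):
        lags = np.arange(5) * 0.15
        msd = MSDCurve(lags, 0.01 - 0.004 * lags, np.array([10, 9, 8, 7, 6]))
        est = fit_diffusion(msd, n_lags=4)
        assert est.D_um2_s == 0.0
        assert est.clamped

    def test_refuses_single_usable_lag(self):
        msd = MSDCurve(np.array([0.0, 0.15, 0.3]), np.array([0.0, 1.0, 2.0]),
                       np.array([3, 2, 0]))
        with pytest.raises(RefusalError):
            fit_diffusion(msd, n_lags=4)


class TestMotionRange:
    def test_l_shaped_path_diagonal(self):
        t = _traj([0.0, 1.0, 1.0], [0.0, 0.0, 1.0])
        assert motion_range(t) == pytest.approx(np.sqrt(2.0))

    def test_stationary_is_zero(self):
        t = _traj([1.0, 1.0, 1.0], [5.0, 5.0, 5.0])
        assert motion_range(t) == 0.0

    def test_single_point_refused(self):
        with pytest.raises(RefusalError):
            motion_range(_traj([0.0], [0.0]))

    def test_matches_all_pairs_maximum(self, rng):
        traj = random_trajectory(rng, 20)
        brute = max(
            np.hypot(traj.x_um[i] - traj.x_um[j], traj.y_um[i] - traj.y_um[j])
            for i in range(20) for j in range(20))
        assert motion_range(traj) == pytest.approx(brute)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0), st.integers(0, 10 ** 6))
    def test_scale_covariance(self, c, seed):
        rng = np.random.default_rng(seed)
        traj = random_trajectory(rng, 12)
        scaled = Trajectory(0, traj.frames, c * traj.x_um, c * traj.y_um,
                            traj.intensity)
        assert motion_range(scaled) == pytest.approx(c * motion_range(traj),
                                                     rel=1e-9)
        d0 = fit_diffusion(compute_msd(traj, 4, 0.15)).D_um2_s
        d1 = fit_diffusion(compute_msd(scaled, 4, 0.15)).D_um2_s
        assert d1 == pytest.approx(c ** 2 * d0, rel=1e-9, abs=1e-15)


class TestPopulationPeak:
    def test_recovers_motion_range_center(self, rng):
        values = rng.normal(0.40, 0.05, 10_000)
        fit = fit_population_peak(values, "motion_range")
        assert fit.peak == pytest.approx(0.40, abs=0.01)

    def test_recovers_diffusion_center(self, rng):
        values = rng.normal(1.97e-3, 0.3e-3, 10_000)
        fit = fit_population_peak(values, "diffusion_coefficient")
        assert fit.peak == pytest.approx(1.97e-3, rel=0.05)

    def test_counts_sum_to_number_of_values(self, rng):
        values = rng.normal(1.0, 0.1, 500)
        fit = fit_population_peak(values, "x")
        assert fit.counts.sum() == 500
        assert fit.bin_edges[0] <= fit.peak <= fit.bin_edges[-1]

    def test_identical_values_refused(self):
        with pytest.raises(RefusalError, match="zero spread"):
            fit_population_peak(np.full(100, 2.0), "x")

    def test_too_few_values_refused(self):
        with pytest.raises(RefusalError, match="at least 50"):
            fit_population_peak(np.arange(10.0), "x")

    def test_higher_diffusion_shifts_both_peaks_up(self, rng):
        """Monotonicity of G-hat in the true mobility."""
        from pmspt.dynamics import analyze_trajectories
        from pmspt.simulate import TirfSimParams, simulate_tirf_movie
        from pmspt.tracking import dataframe_to_trajectories
        peaks = {}
        for d in (1e-3, 4e-3):
            p = TirfSimParams(field_size_px=(256, 256), diffusion_um2_s=d,
                              dwell_mean_s=np.inf, n_initial=150,
                              birth_rate_per_frame=0.0, n_frames=80, seed=9)
            _, truth = simulate_tirf_movie(p, render=False)
            trajs = dataframe_to_trajectories(
                truth.positions.assign(intensity=1.0))
            per = analyze_trajectories(trajs, 0.15)
            peaks[d] = (fit_population_peak(per["D_um2_s"], "D").peak,
                        fit_population_peak(per["motion_range_um"], "mr").peak)
        assert peaks[4e-3][0] > peaks[1e-3][0]
        assert peaks[4e-3][1] > peaks[1e-3][1]
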