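"""Per-trajectory diffusion analysis and population summaries.

For each trajectory the time-averaged mean square displacement (MSD) is
computed as a function of time lag; free 2D Brownian motion gives
MSD(t) = 4 D t, so the diffusion coefficient is slope/4 of an ordinary
least-squares line through the first few lags (short-lag fitting limits
confinement and noise bias; the intercept absorbs static localization
error). The population of a per-trajectory statistic (diffusion
coefficient or motion range) is summarized by the peak position of a
single Gaussian fitted to its histogram, denoted G-hat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

from .errors import FitError, RefusalError
from .tracking import Trajectory


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory. Lag 0 is included (MSD = 0)."""

    lag_times_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray


@dataclass
class DiffusionEstimate:
    D_um2_s: float
    intercept_um2: float
    r2: float
    n_lags_used: int
    clamped: bool = False   # True when the raw slope was negative


@dataclass
class PopulationFit:
    statistic: str
    bin_edges: np.ndarray
    counts: np.ndarray
    amplitude: float
    peak: float         # G-hat: fitted Gaussian mean
    width_sigma: float
    rmse: float
    n_values: int


def compute_msd(traj: Trajectory, max_lag: int,
                frame_interval_s: float, gap_policy: str = "skip") -> MSDCurve:
    """Time-averaged MSD over lags 1..max_lag (plus the trivial lag 0).

    With the default ``gap_policy="skip"`` a pair (i, i+k) contributes only
    if all k intermediate frames were observed (pairs spanning gap-closed
    stretches are dropped); with ``"span"`` any pair whose frame difference
    is k contributes. ``max_lag`` beyond the trajectory span is truncated.
    """
    if traj.n_points < 2:
        raise RefusalError("MSD needs a trajectory with at least 2 points")
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")
    frames = traj.frames
    span = int(frames[-1] - frames[0])
    max_lag = min(max_lag, span)
    pos = np.stack([traj.x_um, traj.y_um], axis=1)

    msd = np.zeros(max_lag + 1)
    n_pairs = np.zeros(max_lag + 1, dtype=int)
    n_pairs[0] = traj.n_points
    for k in range(1, max_lag + 1):
        if gap_policy == "skip":
            if k >= traj.n_points:
                continue
            dfr = frames[k:] - frames[:-k]
            sel = dfr == k        # strictly-increasing frames => contiguous
            if not np.any(sel):
                continue
            d = pos[k:][sel] - pos[:-k][sel]
        elif gap_policy == "span":
            ii, jj = np.nonzero((frames[None, :] - frames[:, None]) == k)
            if len(ii) == 0:
                continue
            d = pos[jj] - pos[ii]
        else:
            raise ValueError("gap_policy must be 'skip' or 'span'")
        sq = np.einsum("ij,ij->i", d, d)
        msd[k] = sq.mean()
        n_pairs[k] = len(sq)
    lags = np.arange(max_lag + 1) * frame_interval_s
    return MSDCurve(lags, msd, n_pairs)


def fit_diffusion(msd: MSDCurve, n_lags: int = 4) -> DiffusionEstimate:
    """OLS line over the first ``n_lags`` non-zero lags; D = slope / 4.

    A negative slope is clamped to D = 0 and flagged rather than dropped, so
    population counts stay interpretable. Refuses when fewer than 2 lags
    carry displacement pairs.
    """
    usable = np.flatnonzero(msd.n_pairs[1:] > 0) + 1
    usable = usable[usable <= n_lags]
    if len(usable) < 2:
        raise RefusalError("diffusion fit needs at least 2 usable lags")
    t = msd.lag_times_s[usable]
    y = msd.msd_um2[usable]
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    clamped = slope < 0
    D = max(slope, 0.0) / 4.0
    return DiffusionEstimate(float(D), float(intercept), float(r2),
                             len(usable), clamped)


def motion_range(traj: Trajectory) -> float:
    """Largest displacement during the particle's lifetime (um):
    the maximum Euclidean distance over all pairs of visited positions."""
    if traj.n_points < 2:
        raise RefusalError("motion range needs at least 2 points")
    pos = np.stack([traj.x_um, traj.y_um], axis=1)
    return float(pdist(pos).max())


def _gaussian(x, amp, mu, sig):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sig ** 2))


def fit_population_peak(values, statistic: str = "statistic",
                        bins="fd", min_count: int = 50) -> PopulationFit:
    """Histogram a per-trajectory statistic and fit a single Gaussian.

    Returns the fitted peak position G-hat. Freedman–Diaconis binning by
    default. Refuses degenerate inputs (too few values, zero spread) and
    diverged fits (peak escaping the histogram support) instead of
    reporting a meaningless center — multimodality or pathologies should
    surface, not be silently averaged away.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_count:
        raise RefusalError(
            f"population fit needs at least {min_count} values, got {len(values)}")
    if np.ptp(values) == 0:
        raise RefusalError("population fit refused: zero spread (all values equal)")
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(np.average(centers, weights=np.maximum(counts, 1e-9))),
          float(max(values.std(), 1e-12)))
    try:
        popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amp, mu, sig = popt
    sig = abs(float(sig))
    if not (edges[0] <= mu <= edges[-1]):
        raise FitError(
            f"fitted peak {mu:g} escapes the histogram support "
            f"[{edges[0]:g}, {edges[-1]:g}] — distribution may be multimodal")
    rmse = float(np.sqrt(np.mean((counts - _gaussian(centers, *popt)) ** 2)))
    return PopulationFit(statistic, edges, counts, float(amp), float(mu),
                         sig, rmse, len(values))


def analyze_trajectories(trajs: list[Trajectory], frame_interval_s: float,
                         n_lags: int = 4, max_lag: int | None = None
                         ) -> pd.DataFrame:
    """Per-trajectory table: diffusion coefficient, fit quality, motion range.

    Trajectories too short for the fit are skipped (not an error): the
    minimum useful length is n_lags + 1 points.
    """
    if max_lag is None:
        max_lag = n_lags
    rows = []
    for t in trajs:
        if t.n_points < n_lags + 1:
            continue
        try:
            est = fit_diffusion(compute_msd(t, max_lag, frame_interval_s), n_lags)
        except RefusalError:
            continue
        rows.append((t.id, t.n_points, est.D_um2_s, est.intercept_um2,
                     est.r2, est.clamped, motion_range(t)))
    return pd.DataFrame(rows, columns=["id", "n_points", "D_um2_s",
                                       "intercept_um2", "r2", "clamped",
                                       "motion_range_um"])
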