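"""FLIM lifetime fitting and FRET efficiency.

Each pixel of a FLIM acquisition is a histogram of photon arrival times
within a finite window. For a monoexponential decay truncated to the
window W, the mean arrival time is

    m(tau) = tau - W / (exp(W/tau) - 1),

and the maximum-likelihood lifetime estimate solves m(tau) = sample mean —
no instrument response deconvolution, but the window truncation is handled
analytically (a naive mean-arrival estimate systematically underestimates
tau). FRET efficiency from donor (D) and donor+acceptor (DA) lifetimes is
E = (1 - tau_DA / tau_D) * 100 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import RefusalError


@dataclass
class FLIMData:
    """Per-pixel photon-arrival histograms: counts has shape (H, W, n_bins)."""

    counts: np.ndarray
    bin_width_ns: float
    window_ns: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (H, W, n_bins)")
        if self.bin_width_ns <= 0 or self.window_ns <= 0:
            raise ValueError("bin_width_ns and window_ns must be positive")
        n_bins = self.counts.shape[2]
        if abs(n_bins * self.bin_width_ns - self.window_ns) > 1e-6 * self.window_ns:
            raise ValueError("window_ns must equal n_bins * bin_width_ns")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=2)


@dataclass
class LifetimeFit:
    tau_ns: float
    n_photons: int
    ok: bool
    quality: str = "good"    # "good" | "low_photons" | "degenerate"


@dataclass
class LifetimeMap:
    tau_ns: np.ndarray       # nan where unfit
    photons: np.ndarray
    ok: np.ndarray           # boolean fit-success mask


@dataclass
class FretResult:
    tau_donor_ns: float
    tau_da_ns: float
    efficiency_pct: float
    n_rois: int = 1
    negative: bool = False


def truncated_exp_mean(tau_ns: float, window_ns: float) -> float:
    """Mean arrival time of Exp(tau) conditioned on arrival < window."""
    if tau_ns <= 0:
        raise ValueError("tau must be positive")
    x = window_ns / tau_ns
    if x > 700:   # truncation negligible
        return tau_ns
    return tau_ns - window_ns / math.expm1(x)


def _solve_tau(mean_ns: float, window_ns: float, bin_width_ns: float) -> tuple[float, str]:
    """Invert the truncated-exponential mean equation."""
    half = window_ns / 2.0
    if mean_ns >= half - 1e-9:
        # flat (or inverted) histogram: tau unbounded above
        return math.inf, "degenerate"
    if mean_ns <= bin_width_ns * 0.51:
        # essentially all photons in the first bin
        return max(mean_ns, 1e-6), "degenerate"
    lo, hi = bin_width_ns / 100.0, window_ns * 1e3
    tau = brentq(lambda t: truncated_exp_mean(t, window_ns) - mean_ns, lo, hi,
                 xtol=1e-12, rtol=1e-12)
    quality = "good" if tau >= 2 * bin_width_ns else "degenerate"
    return tau, quality


def fit_pixel_lifetime(histogram: np.ndarray, bin_width_ns: float,
                       window_ns: float | None = None,
                       min_photons: int = 100,
                       method: str = "mle") -> LifetimeFit:
    """Monoexponential lifetime from one pixel's arrival histogram.

    ``method="mle"`` (default) solves the truncated-exponential mean
    equation; ``method="lsq"`` is a least-squares line on log-counts,
    provided as a cross-check (it ignores truncation and Poisson weights).
    Pixels with fewer than ``min_photons`` photons are flagged unfit.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1:
        raise ValueError("histogram must be 1D")
    if window_ns is None:
        window_ns = len(hist) * bin_width_ns
    n = int(hist.sum())
    if n < min_photons:
        return LifetimeFit(math.nan, n, False, "low_photons")
    centers = (np.arange(len(hist)) + 0.5) * bin_width_ns
    if method == "mle":
        mean = float(np.dot(hist, centers) / n)
        tau, quality = _solve_tau(mean, window_ns, bin_width_ns)
        return LifetimeFit(tau, n, math.isfinite(tau), quality)
    if method == "lsq":
        sel = hist > 0
        if sel.sum() < 2:
            return LifetimeFit(math.nan, n, False, "degenerate")
        slope = np.polyfit(centers[sel], np.log(hist[sel]), 1, w=np.sqrt(hist[sel]))[0]
        if slope >= 0:
            return LifetimeFit(math.inf, n, False, "degenerate")
        return LifetimeFit(-1.0 / slope, n, True, "good")
    raise ValueError("method must be 'mle' or 'lsq'")


def naive_mean_lifetime(histogram: np.ndarray, bin_width_ns: float) -> float:
    """Mean arrival time, uncorrected for window truncation (biased low)."""
    hist = np.asarray(histogram, dtype=float)
    n = hist.sum()
    if n == 0:
        raise RefusalError("empty histogram")
    centers = (np.arange(len(hist)) + 0.5) * bin_width_ns
    return float(np.dot(hist, centers) / n)


def fit_lifetime_map(data: FLIMData, min_photons: int = 100) -> LifetimeMap:
    """Per-pixel ML lifetimes over the acquisition. Unfit pixels are nan."""
    h, w, _ = data.counts.shape
    photons = data.total_counts.astype(np.int64)
    centers = data.bin_centers_ns
    tau = np.full((h, w), np.nan)
    ok = np.zeros((h, w), dtype=bool)
    sums = np.tensordot(data.counts.astype(float), centers, axes=([2], [0]))
    means = np.divide(sums, photons, out=np.zeros_like(sums),
                      where=photons > 0)
    for i in range(h):
        for j in range(w):
            if photons[i, j] < min_photons:
                continue
            t, quality = _solve_tau(means[i, j], data.window_ns,
                                    data.bin_width_ns)
            if math.isfinite(t) and quality == "good":
                tau[i, j] = t
                ok[i, j] = True
    return LifetimeMap(tau, photons, ok)


def roi_lifetime(lt_map: LifetimeMap, roi_mask: np.ndarray
                 ) -> tuple[float, float, int]:
    """Photon-weighted mean lifetime +/- SD over an ROI's fit pixels."""
    roi = np.asarray(roi_mask, dtype=bool)
    sel = roi & lt_map.ok
    n = int(sel.sum())
    if n == 0:
        raise RefusalError("ROI contains no successfully fit pixel")
    taus = lt_map.tau_ns[sel]
    wts = lt_map.photons[sel].astype(float)
    mean = float(np.average(taus, weights=wts))
    var = float(np.average((taus - mean) ** 2, weights=wts))
    return mean, math.sqrt(var), n


def render_lifetime_map(lt_map: LifetimeMap, tau_min_ns: float = 2.1,
                        tau_max_ns: float = 2.7, cmap: str = "jet"
                        ) -> np.ndarray:
    """Fixed-scale pseudo-color render: navy at tau_min, red at tau_max.

    The scale is absolute (identical lifetimes map to identical colors in
    every image); out-of-range lifetimes are clamped; unfit pixels black.
    Returns an (H, W, 3) uint8 RGB image.
    """
    import matplotlib
    cm = matplotlib.colormaps[cmap]
    norm = (lt_map.tau_ns - tau_min_ns) / (tau_max_ns - tau_min_ns)
    norm = np.clip(np.nan_to_num(norm, nan=0.0), 0.0, 1.0)
    rgb = (cm(norm)[..., :3] * 255).astype(np.uint8)
    rgb[~lt_map.ok] = 0
    return rgb


def fret_efficiency(tau_donor_ns: float, tau_da_ns: float) -> float:
    """E (%) = (1 - tau_DA / tau_D) * 100 from mean lifetimes.

    May be negative when the donor+acceptor lifetime exceeds the donor-only
    lifetime; the value is reported as-is (callers can flag it) rather than
    clipped.
    """
    if tau_donor_ns <= 0 or tau_da_ns <= 0:
        raise RefusalError("lifetimes must be strictly positive")
    return (1.0 - tau_da_ns / tau_donor_ns) * 100.0


def fret_from_rois(donor_taus, da_taus) -> dict:
    """FRET efficiency both ways the field averages it.

    ``per_roi_pct``: E computed per matched ROI pair then averaged;
    ``pooled_pct``: E from the pooled mean lifetimes. The two differ
    slightly whenever lifetimes vary between ROIs.
    """
    donor_taus = np.asarray(donor_taus, dtype=float)
    da_taus = np.asarray(da_taus, dtype=float)
    pooled = fret_efficiency(float(donor_taus.mean()), float(da_taus.mean()))
    if len(donor_taus) == len(da_taus):
        per_roi = float(np.mean([fret_efficiency(d, a)
                                 for d, a in zip(donor_taus, da_taus)]))
    else:
        per_roi = pooled
    return {"pooled_pct": pooled, "per_roi_pct": per_roi,
            "n_donor": len(donor_taus), "n_da": len(da_taus)}
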