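"""Synthetic microscopy with exact ground truth.

Three generators, one per acquisition modality:

* :func:`simulate_tirf_movie` — single membrane particles undergoing 2D
  Brownian diffusion, born by a memoryless (Poisson) process, living for
  exponentially distributed dwell times, rendered as Gaussian PSF spots on an
  EM-CCD-like camera (Poisson shot noise + Gaussian read noise, 16-bit).
* :func:`simulate_confocal_stack` — a cell phantom with a bright plasma
  membrane shell and a controllable cytoplasmic (internalized) signal
  fraction, sliced into a z-stack.
* :func:`simulate_flim` — per-pixel TCSPC photon-arrival histograms drawn
  from monoexponential decays truncated to the acquisition window.

Every generator takes a parameter dataclass with a ``seed``; identical
parameters give bit-identical output. The hidden state (particle positions,
lifetimes, noiseless signal split, true lifetimes) is returned as a
ground-truth object so downstream estimators can be validated by parameter
recovery instead of against undeposited raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageStack, ZStack, write_json


# --------------------------------------------------------------------------
# TIRF movie
# --------------------------------------------------------------------------

@dataclass
class TirfSimParams:
    """Conditions of a simulated VA-TIRFM acquisition.

    Defaults mirror the measured regime of membrane receptor imaging: a
    diffusion coefficient of 2e-3 um^2/s, exponential dwell times of ~2 s,
    and 0.15 s frame intervals. The pixel size (0.1 um/px) and the camera
    parameters are not constrained by that regime and are package defaults.
    """

    field_size_px: tuple[int, int] = (128, 128)   # (height, width)
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.15
    n_frames: int = 100
    diffusion_um2_s: float = 2e-3
    dwell_mean_s: float = 2.0
    birth_rate_per_frame: float = 1.0
    n_initial: int = 0                 # particles already on the membrane at t=0
    psf_sigma_px: float = 1.2
    photons_per_spot: float = 400.0
    background_photons: float = 20.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.field_size_px
        if h <= 0 or w <= 0:
            raise ValueError("field_size_px must be strictly positive")
        for name in ("pixel_size_um", "frame_interval_s", "dwell_mean_s",
                     "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("diffusion_um2_s", "birth_rate_per_frame", "n_initial",
                     "photons_per_spot", "background_photons", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")


@dataclass
class TirfGroundTruth:
    """Hidden particle records of a simulated movie.

    ``particles`` has one row per particle (including those whose lifetime
    fell entirely between frames): continuous birth/death times, the frame
    range in which the particle was rendered, and censoring flags.
    ``positions`` has one row per particle per rendered frame, in um.
    """

    particles: pd.DataFrame
    positions: pd.DataFrame
    true_diffusion_um2_s: float
    true_dwell_mean_s: float
    params: TirfSimParams

    def dwell_values(self, uncensored_only: bool = True) -> np.ndarray:
        """True continuous lifetimes (s) of born particles.

        Particles seeded at t=0 are excluded (their birth is unobserved);
        with ``uncensored_only`` those still alive at movie end or removed by
        a field-boundary exit are excluded as well.
        """
        p = self.particles
        sel = ~p["start_censored"]
        if uncensored_only:
            sel &= ~p["end_censored"] & ~p["boundary_exit"]
        return p.loc[sel, "lifetime_s"].to_numpy()

    def trajectories_frame(self) -> pd.DataFrame:
        return self.positions.copy()

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        self.particles.to_csv(out_dir / "truth_particles.csv", index=False)
        self.positions.to_csv(out_dir / "truth_positions.csv", index=False)
        write_json(out_dir / "sim_params.json", asdict(self.params))


def render_spots(shape: tuple[int, int], x_px: np.ndarray, y_px: np.ndarray,
                 photons: np.ndarray | float, psf_sigma_px: float) -> np.ndarray:
    """Expected (noiseless) photon image of Gaussian spots.

    Each spot integrates to its photon budget on the discrete grid (spots
    overlapping the field edge lose the clipped part). x is column, y is row,
    pixel centers at integer coordinates.
    """
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    x_px = np.atleast_1d(np.asarray(x_px, dtype=float))
    y_px = np.atleast_1d(np.asarray(y_px, dtype=float))
    photons = np.broadcast_to(np.asarray(photons, dtype=float), x_px.shape)
    r = max(3, int(math.ceil(4 * psf_sigma_px)))
    ax = np.arange(-r, r + 1)
    for x, y, n_ph in zip(x_px, y_px, photons):
        cx, cy = int(round(x)), int(round(y))
        gx = np.exp(-((ax + cx - x) ** 2) / (2 * psf_sigma_px ** 2))
        gy = np.exp(-((ax + cy - y) ** 2) / (2 * psf_sigma_px ** 2))
        stamp = np.outer(gy, gx)
        stamp *= n_ph / stamp.sum()
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        img[y0:y1, x0:x1] += stamp[y0 - (cy - r):y1 - (cy - r),
                                   x0 - (cx - r):x1 - (cx - r)]
    return img


def _camera(expected: np.ndarray, read_noise_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(expected).astype(float)
    if read_noise_sd > 0:
        counts += rng.normal(0.0, read_noise_sd, size=counts.shape)
    return np.clip(np.round(counts), 0, 65535).astype(np.uint16)


def _sample_tirf_particles(p: TirfSimParams, rng: np.random.Generator):
    """Draw birth times, lifetimes and Brownian paths for every particle."""
    dt = p.frame_interval_s
    h, w = p.field_size_px
    fw_um = w * p.pixel_size_um
    fh_um = h * p.pixel_size_um
    movie_end = (p.n_frames - 1) * dt
    step_sd = math.sqrt(2.0 * p.diffusion_um2_s * dt)

    birth_times = [np.zeros(p.n_initial)]
    start_censored = [np.ones(p.n_initial, dtype=bool)]
    n_new = rng.poisson(p.birth_rate_per_frame, size=p.n_frames)
    for f in range(p.n_frames):
        birth_times.append((f + rng.random(n_new[f])) * dt)
        start_censored.append(np.zeros(n_new[f], dtype=bool))
    birth_times = np.concatenate(birth_times)
    start_censored = np.concatenate(start_censored)

    particles, positions = [], []
    for pid, (t_birth, censored0) in enumerate(zip(birth_times, start_censored)):
        lifetime = (math.inf if math.isinf(p.dwell_mean_s)
                    else rng.exponential(p.dwell_mean_s))
        t_death = t_birth + lifetime
        first = int(math.ceil(t_birth / dt - 1e-12))
        last = p.n_frames - 1 if math.isinf(t_death) else \
            int(math.ceil(t_death / dt - 1e-12)) - 1
        last = min(last, p.n_frames - 1)
        end_censored = t_death > movie_end + 1e-12
        boundary_exit = False

        xs, ys = [], []
        if first <= last:
            x = rng.uniform(0.0, fw_um)
            y = rng.uniform(0.0, fh_um)
            for k in range(first, last + 1):
                if k > first:
                    x += rng.normal(0.0, step_sd)
                    y += rng.normal(0.0, step_sd)
                    if not (0.0 <= x < fw_um and 0.0 <= y < fh_um):
                        # leaving the field kills the particle (recorded death)
                        boundary_exit = True
                        last = k - 1
                        t_death = k * dt
                        end_censored = False
                        break
                xs.append(x)
                ys.append(y)
        n_visible = len(xs)
        particles.append((pid, t_birth, t_death, t_death - t_birth,
                          first if n_visible else -1,
                          first + n_visible - 1 if n_visible else -1,
                          n_visible, bool(censored0), bool(end_censored),
                          boundary_exit))
        for k, (x, y) in enumerate(zip(xs, ys)):
            positions.append((pid, first + k, x, y))

    particles = pd.DataFrame(
        particles, columns=["id", "t_birth_s", "t_death_s", "lifetime_s",
                            "birth_frame", "death_frame", "n_frames_visible",
                            "start_censored", "end_censored", "boundary_exit"])
    positions = pd.DataFrame(positions, columns=["id", "frame", "x_um", "y_um"])
    return particles, positions


def simulate_tirf_movie(params: TirfSimParams,
                        render: bool = True) -> tuple[ImageStack | None, TirfGroundTruth]:
    """Simulate a TIRF single-particle movie with exact ground truth.

    With ``render=False`` only the hidden particle records are produced
    (useful for statistical checks that do not need pixels).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    particles, positions = _sample_tirf_particles(params, rng)
    truth = TirfGroundTruth(particles, positions, params.diffusion_um2_s,
                            params.dwell_mean_s, params)
    if not render:
        return None, truth

    h, w = params.field_size_px
    by_frame = dict(tuple(positions.groupby("frame"))) if len(positions) else {}
    frames = np.empty((params.n_frames, h, w), dtype=np.uint16)
    for f in range(params.n_frames):
        expected = np.full((h, w), params.background_photons, dtype=float)
        grp = by_frame.get(f)
        if grp is not None and params.photons_per_spot > 0:
            expected += render_spots(
                (h, w),
                grp["x_um"].to_numpy() / params.pixel_size_um,
                grp["y_um"].to_numpy() / params.pixel_size_um,
                params.photons_per_spot, params.psf_sigma_px)
        frames[f] = _camera(expected, params.read_noise_sd, rng)
    stack = ImageStack(frames, params.pixel_size_um, params.frame_interval_s)
    return stack, truth


# --------------------------------------------------------------------------
# Confocal z-stack
# --------------------------------------------------------------------------

@dataclass
class ConfocalSimParams:
    """A cell phantom for internalization quantification.

    The cell is a vertical cylinder: every lateral slice shows the same
    bright membrane annulus with cytoplasmic signal (a uniform pool plus
    puncta) inside it. Per slice, a fraction ``internal_fraction`` of the
    noiseless photon budget is allocated to the cytoplasm and the rest to
    the membrane annulus, so the cytoplasm/whole-cell intensity ratio equals
    ``internal_fraction`` exactly both per slice and over the volume.
    """

    n_slices: int = 24
    shape_px: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.2
    z_step_um: float = 0.5
    cell_radius_um: float = 8.0
    shell_half_width_px: float = 1.0
    internal_fraction: float = 0.1
    apical_slice: int = 2              # empty slices above the cell top
    n_cell_slices: int = 18
    signal_per_slice: float = 2e5      # photons per lateral slice
    uniform_cyto_weight: float = 0.5   # split of cytoplasmic budget: pool vs puncta
    puncta_per_slice: int = 30
    punctum_sigma_px: float = 1.5
    interior_margin_px: float = 9.0    # keep cytoplasm clear of the annulus
    blur_sigma_px: float = 0.5
    background_photons: float = 5.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.internal_fraction <= 1.0):
            raise ValueError("internal_fraction must lie in [0, 1]")
        if self.n_slices < 2:
            raise ValueError("n_slices must be at least 2")
        for name in ("pixel_size_um", "z_step_um", "cell_radius_um",
                     "shell_half_width_px", "signal_per_slice"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.apical_slice + self.n_cell_slices > self.n_slices:
            raise ValueError("cell does not fit in the stack "
                             "(apical_slice + n_cell_slices > n_slices)")
        if not (0.0 <= self.uniform_cyto_weight <= 1.0):
            raise ValueError("uniform_cyto_weight must lie in [0, 1]")


@dataclass
class ConfocalGroundTruth:
    internal_fraction_true: float      # realized noiseless cytoplasm/whole ratio
    cell_mask: np.ndarray              # 2D footprint of the cell
    pm_mask: np.ndarray                # 2D annulus mask
    cyto_mask: np.ndarray              # 2D interior mask
    apical_slice: int
    params: ConfocalSimParams


def simulate_confocal_stack(params: ConfocalSimParams
                            ) -> tuple[ZStack, ConfocalGroundTruth]:
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.shape_px
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dist = np.hypot(yy - cy, xx - cx)
    r_px = params.cell_radius_um / params.pixel_size_um

    pm = np.abs(dist - r_px) <= params.shell_half_width_px
    interior_r = r_px - params.interior_margin_px
    if interior_r <= 2:
        raise ValueError("interior_margin_px leaves no cytoplasm")
    cyto = dist <= interior_r
    cell = dist <= r_px + params.shell_half_width_px
    f = params.internal_fraction
    S = params.signal_per_slice

    noiseless = np.zeros((params.n_slices, h, w), dtype=float)
    cyto_sum = whole_sum = 0.0
    lo = params.apical_slice
    hi = lo + params.n_cell_slices
    for z in range(lo, hi):
        img = np.zeros((h, w), dtype=float)
        img[pm] += (1.0 - f) * S / pm.sum()
        if f > 0:
            img[cyto] += f * params.uniform_cyto_weight * S / cyto.sum()
            n_p = params.puncta_per_slice
            if n_p > 0 and params.uniform_cyto_weight < 1.0:
                # puncta centers uniform in the interior disk
                rad = interior_r * np.sqrt(rng.random(n_p))
                ang = rng.uniform(0, 2 * np.pi, n_p)
                px = cx + rad * np.cos(ang)
                py = cy + rad * np.sin(ang)
                per = f * (1.0 - params.uniform_cyto_weight) * S / n_p
                img += render_spots((h, w), px, py, per, params.punctum_sigma_px)
        # truth from the allocation: where the protein is, before optics
        cyto_sum += f * S
        whole_sum += S
        if params.blur_sigma_px > 0:
            img = ndi.gaussian_filter(img, params.blur_sigma_px)
        noiseless[z] = img

    truth_fraction = cyto_sum / whole_sum if whole_sum > 0 else 0.0
    slices = np.empty_like(noiseless, dtype=np.uint16)
    for z in range(params.n_slices):
        slices[z] = _camera(noiseless[z] + params.background_photons,
                            params.read_noise_sd, rng)
    stack = ZStack(slices, params.z_step_um, params.pixel_size_um)
    truth = ConfocalGroundTruth(truth_fraction, cell, pm, cell & ~pm,
                                params.apical_slice, params)
    return stack, truth


# --------------------------------------------------------------------------
# FLIM decays
# --------------------------------------------------------------------------

@dataclass
class FlimSimParams:
    """TCSPC acquisition over a map of true lifetimes (ns)."""

    lifetime_map_ns: np.ndarray = field(
        default_factory=lambda: np.full((16, 16), 2.53))
    photons_per_pixel: float = 1e4
    window_ns: float = 25.0
    n_bins: int = 250
    seed: int = 0

    def validate(self) -> None:
        tau = np.asarray(self.lifetime_map_ns, dtype=float)
        if tau.ndim != 2:
            raise ValueError("lifetime_map_ns must be a 2D map")
        if not np.all(tau > 0):
            raise ValueError("lifetime_map_ns must be strictly positive")
        if self.window_ns <= 0:
            raise ValueError("window_ns must be strictly positive")
        if self.window_ns <= tau.max():
            raise ValueError("window_ns must exceed the largest lifetime")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.photons_per_pixel < 0:
            raise ValueError("photons_per_pixel must be non-negative")


def simulate_flim(params: FlimSimParams):
    """Per-pixel photon-arrival histograms from truncated exponential decays.

    Arrival times are drawn from Exp(tau) conditioned on t < window (photons
    outside the window are never recorded by the hardware), then binned.
    Returns a :class:`pmspt.flim.FLIMData`.
    """
    from .flim import FLIMData  # local import to avoid a cycle

    params.validate()
    rng = np.random.default_rng(params.seed)
    tau_map = np.asarray(params.lifetime_map_ns, dtype=float)
    h, w = tau_map.shape
    n_bins = params.n_bins
    bin_width = params.window_ns / n_bins

    counts_per_px = rng.poisson(params.photons_per_pixel, size=(h, w))
    hist = np.zeros((h, w, n_bins), dtype=np.uint32)
    flat_tau = tau_map.ravel()
    flat_counts = counts_per_px.ravel()
    for tau in np.unique(flat_tau):
        sel = np.flatnonzero(flat_tau == tau)
        n_tot = int(flat_counts[sel].sum())
        if n_tot == 0:
            continue
        u = rng.random(n_tot)
        t = -tau * np.log1p(-u * (1.0 - math.exp(-params.window_ns / tau)))
        bins = np.minimum((t / bin_width).astype(np.int64), n_bins - 1)
        pix = np.repeat(sel, flat_counts[sel])
        flat = np.bincount(pix * n_bins + bins, minlength=h * w * n_bins)
        hist += flat.reshape(h, w, n_bins).astype(np.uint32)
    return FLIMData(hist, bin_width_ns=bin_width, window_ns=params.window_ns)
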