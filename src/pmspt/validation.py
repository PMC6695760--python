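"""Parameter-recovery experiments on the simulator.

These are the package's self-checks: each function simulates data with
known ground truth at the measured regime of membrane receptor imaging
(D near 2e-3 um^2/s, exponential dwell ~1.5-2 s, 0.15 s frames), runs the
full analysis path, and reports the recovered quantity next to the truth.
Both the test suite and scripts/acceptance.py call these.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .dwell import dwell_from_trajectories, estimate_dwell_mean, summarize_dwell
from .dynamics import analyze_trajectories, fit_population_peak
from .flim import fit_lifetime_map, fret_efficiency, roi_lifetime
from .internalize import measure_internalization
from .simulate import (ConfocalSimParams, FlimSimParams, TirfSimParams,
                       simulate_confocal_stack, simulate_flim,
                       simulate_tirf_movie)
from .tracking import dataframe_to_trajectories, detect_movie, link_spots


def _seed(base: int, offset: int) -> int:
    return int((base * 1_000_003 + offset) % (2 ** 31))


# --------------------------------------------------------------------------
# Diffusion-coefficient recovery (population G-hat)
# --------------------------------------------------------------------------

def diffusion_recovery(seed: int, true_d: float = 2e-3, n_particles: int = 560,
                       n_frames: int = 150, field: int = 384,
                       n_lags: int = 4) -> dict:
    """Recover the diffusion coefficient's population peak two ways.

    ``ghat_truth`` fits per-trajectory D on the simulator's true positions
    (isolating the estimator); ``ghat_tracked`` runs detection + linking on
    the rendered movie first (the full pipeline, including localization
    error, which the MSD-fit intercept absorbs). Long dwell times give
    ~150-frame tracks so the per-trajectory estimates are tight enough for
    a meaningful Gaussian peak.
    """
    params = TirfSimParams(
        field_size_px=(field, field), n_frames=n_frames,
        diffusion_um2_s=true_d, dwell_mean_s=1e6, birth_rate_per_frame=0.0,
        n_initial=n_particles, photons_per_spot=400.0, background_photons=20.0,
        read_noise_sd=2.0, seed=_seed(seed, 1))
    stack, truth = simulate_tirf_movie(params)
    dt = params.frame_interval_s

    true_trajs = dataframe_to_trajectories(
        truth.positions.assign(intensity=1.0))
    per_true = analyze_trajectories(
        [t for t in true_trajs if t.n_points >= 20], dt, n_lags=n_lags)
    ghat_truth = fit_population_peak(per_true["D_um2_s"],
                                     "diffusion_coefficient").peak

    dets = detect_movie(stack, params.psf_sigma_px, snr_threshold=5.0)
    trajs = link_spots(dets, max_disp_px=2.0, max_gap_frames=1,
                       min_length=20, pixel_size_um=params.pixel_size_um)
    per_tracked = analyze_trajectories(trajs, dt, n_lags=n_lags)
    ghat_tracked = fit_population_peak(per_tracked["D_um2_s"],
                                       "diffusion_coefficient").peak
    return {
        "true_D_um2_s": true_d,
        "ghat_truth_um2_s": float(ghat_truth),
        "ghat_tracked_um2_s": float(ghat_tracked),
        "n_true_trajectories": int(len(per_true)),
        "n_tracked_trajectories": int(len(per_tracked)),
        "motion_range_peak_um": float(
            fit_population_peak(per_tracked["motion_range_um"],
                                "motion_range").peak),
    }


# --------------------------------------------------------------------------
# Dwell-time recovery
# --------------------------------------------------------------------------

def dwell_recovery(seed: int, dwell_mean_s: float = 2.0,
                   n_frames: int = 760, field: int = 160,
                   birth_rate: float = 2.5, min_length: int = 2) -> dict:
    """Recover an exponential membrane dwell mean through the full pipeline.

    Particles are born throughout the movie, tracked at SNR ~9, and their
    dwell records (longest half-max run) summarized. The corrected mean
    comes from the left-truncated geometric MLE; the plain arithmetic mean
    is reported alongside (it carries the known +min_length*Dt acquisition
    bias).
    """
    params = TirfSimParams(
        field_size_px=(field, field), n_frames=n_frames,
        diffusion_um2_s=2e-3, dwell_mean_s=dwell_mean_s,
        birth_rate_per_frame=birth_rate, photons_per_spot=400.0,
        background_photons=20.0, read_noise_sd=2.0, seed=_seed(seed, 2))
    stack, truth = simulate_tirf_movie(params)
    dt = params.frame_interval_s

    dets = detect_movie(stack, params.psf_sigma_px, snr_threshold=5.0)
    trajs = link_spots(dets, max_disp_px=2.5, max_gap_frames=2,
                       min_length=min_length,
                       pixel_size_um=params.pixel_size_um)
    records = dwell_from_trajectories(trajs, stack.n_frames, dt)
    summary = summarize_dwell(records)
    corrected = estimate_dwell_mean(records, dt, min_frames=min_length)
    true_lifetimes = truth.dwell_values(uncensored_only=True)
    return {
        "true_mean_s": dwell_mean_s,
        "corrected_mean_s": float(corrected),
        "plain_mean_s": float(summary.mean_s),
        "n_uncensored": int(summary.n),
        "n_censored": int(summary.n_censored),
        "truth_mean_of_lifetimes_s": float(true_lifetimes.mean()),
        "n_true_particles": int(len(true_lifetimes)),
    }


# --------------------------------------------------------------------------
# Detection precision/recall
# --------------------------------------------------------------------------

def detection_quality(seed: int, n_particles: int = 120, field: int = 256,
                      n_frames: int = 40, match_radius_px: float = 1.0) -> dict:
    """Precision and recall of spot detection against ground truth.

    One-to-one greedy matching within ``match_radius_px`` of the true
    positions, frame by frame, evaluated in the field interior (a spot
    whose fit window falls off the edge is undetectable by construction).
    Density is ~0.0018 spots/px^2 (0.18 spots/um^2 at 0.1 um/px), the
    sparse labeling single-particle imaging requires: a single-Gaussian
    detector cannot separate spots closer than ~2 PSF widths, so precision
    and recall degrade gracefully as density approaches that limit.
    """
    params = TirfSimParams(
        field_size_px=(field, field), n_frames=n_frames,
        diffusion_um2_s=2e-3, dwell_mean_s=1e6, birth_rate_per_frame=0.0,
        n_initial=n_particles, photons_per_spot=400.0,
        background_photons=20.0, read_noise_sd=2.0, seed=_seed(seed, 3))
    stack, truth = simulate_tirf_movie(params)
    px = params.pixel_size_um

    tp = fp = fn = 0
    margin = 4.0
    by_frame = dict(tuple(truth.positions.groupby("frame")))
    dets = detect_movie(stack, params.psf_sigma_px, snr_threshold=5.0)
    for f in range(n_frames):
        grp = by_frame.get(f)
        true_xy = (np.stack([grp["x_um"], grp["y_um"]], axis=1) / px
                   if grp is not None else np.empty((0, 2)))
        det_xy = np.array([[d.x, d.y] for d in dets[f]]).reshape(-1, 2)
        true_xy = true_xy[np.all((true_xy >= margin)
                                 & (true_xy < field - margin), axis=1)]
        if len(det_xy):
            det_xy = det_xy[np.all((det_xy >= margin)
                                   & (det_xy < field - margin), axis=1)]
        if len(true_xy) == 0 or len(det_xy) == 0:
            fp += len(det_xy)
            fn += len(true_xy)
            continue
        tree = cKDTree(true_xy)
        pairs = tree.query_ball_point(det_xy, match_radius_px)
        cand = sorted(
            (np.linalg.norm(det_xy[i] - true_xy[j]), i, j)
            for i, js in enumerate(pairs) for j in js)
        used_d: set = set()
        used_t: set = set()
        for _, i, j in cand:
            if i in used_d or j in used_t:
                continue
            used_d.add(i)
            used_t.add(j)
        tp += len(used_d)
        fp += len(det_xy) - len(used_d)
        fn += len(true_xy) - len(used_t)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"precision": float(precision), "recall": float(recall),
            "n_true": int(tp + fn), "n_detected": int(tp + fp),
            "density_per_px2": n_particles / field ** 2}


# --------------------------------------------------------------------------
# Internalization recovery
# --------------------------------------------------------------------------

def internalization_recovery(seed: int,
                             fractions=(0.0, 0.1, 0.25, 0.5, 1.0)) -> dict:
    """Measured internalized fraction vs the simulator's set fraction."""
    measured = {}
    for i, f in enumerate(fractions):
        params = ConfocalSimParams(internal_fraction=f, seed=_seed(seed, 10 + i))
        stack, truth = simulate_confocal_stack(params)
        result = measure_internalization(stack)
        measured[f] = {"measured": float(result.fraction),
                       "true_noiseless": float(truth.internal_fraction_true),
                       "n_slices": result.n_slices}
    return measured


# --------------------------------------------------------------------------
# FLIM lifetime and FRET recovery
# --------------------------------------------------------------------------

def flim_recovery(seed: int, taus=(2.1, 2.36, 2.53, 2.7),
                  photons: float = 1e4, map_size: int = 24) -> dict:
    """Per-pixel lifetime recovery across the rainbow-scale range,
    plus the donor / donor+acceptor FRET experiment."""
    out = {"taus": {}}
    for i, tau in enumerate(taus):
        params = FlimSimParams(
            lifetime_map_ns=np.full((map_size, map_size), float(tau)),
            photons_per_pixel=photons, seed=_seed(seed, 20 + i))
        data = simulate_flim(params)
        lt_map = fit_lifetime_map(data)
        roi = np.ones(lt_map.tau_ns.shape, dtype=bool)
        mean, sd, n = roi_lifetime(lt_map, roi)
        out["taus"][tau] = {"fitted_ns": float(mean), "sd_ns": float(sd),
                            "n_pixels": int(n)}
    tau_d = out["taus"][2.53]["fitted_ns"]
    tau_da = out["taus"][2.36]["fitted_ns"]
    out["fret"] = {
        "tau_donor_ns": tau_d,
        "tau_da_ns": tau_da,
        "efficiency_pct": float(fret_efficiency(tau_d, tau_da)),
        "efficiency_design_pct": float(fret_efficiency(2.53, 2.36)),
    }
    return out
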