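"""Kymographs and plasma-membrane dwell times.

Dwell time is operationalized from tracked particles: a particle's
fluorescence trace (fitted amplitude per frame) is normalized to its
maximum and the dwell is the length of the longest contiguous run above a
half-max threshold, times the frame interval. Tracks alive at the first or
last movie frame are flagged censored and excluded from mean dwell. The
kymograph (position-along-a-line vs time image) is kept as a visualization
and cross-check of the same residence events.

Because tracks shorter than the tracker's minimum length are unobservable
and frames are discrete, the arithmetic mean of observed dwells
overestimates an exponential dwell mean by about (min_length Dt). The
exact correction, a geometric maximum-likelihood estimator with left
truncation, is provided as :func:`estimate_dwell_mean`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import RefusalError
from .io import ImageStack
from .tracking import Trajectory


@dataclass
class Kymograph:
    data: np.ndarray            # (n_positions, n_frames)
    line: tuple[tuple[float, float], tuple[float, float]]
    frame_interval_s: float
    sample_spacing_px: float = 1.0


@dataclass
class DwellRecord:
    traj_id: int
    dwell_s: float
    censored: bool
    n_frames_above: int
    trace: np.ndarray = field(repr=False, default=None)


@dataclass
class DwellSummary:
    label: str
    mean_s: float
    sd_s: float
    n: int
    n_censored: int


def build_kymograph(stack: ImageStack, line, width_px: int = 1) -> Kymograph:
    """Sample intensity along a line in every frame (one column per frame).

    Bilinear interpolation at ~1 px spacing along the line, averaged over
    ``width_px`` parallel offsets perpendicular to it.
    """
    (x0, y0), (x1, y1) = line
    h, w = stack.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError("line endpoints must lie inside the field")
    length = math.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("zero-length line")
    n_samples = int(math.ceil(length)) + 1
    t = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    # unit normal for the width averaging
    nx, ny = -(y1 - y0) / length, (x1 - x0) / length
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    cols_x = xs[None, :] + offsets[:, None] * nx
    cols_y = ys[None, :] + offsets[:, None] * ny
    coords = np.stack([cols_y.ravel(), cols_x.ravel()])  # (row, col) order
    data = np.empty((n_samples, stack.n_frames))
    for f in range(stack.n_frames):
        vals = ndi.map_coordinates(stack.frames[f].astype(float), coords,
                                   order=1, mode="nearest")
        data[:, f] = vals.reshape(width_px, n_samples).mean(axis=0)
    return Kymograph(data, ((x0, y0), (x1, y1)), stack.frame_interval_s,
                     sample_spacing_px=length / (n_samples - 1))


def trajectory_trace(traj: Trajectory, n_frames: int) -> np.ndarray:
    """Full-movie-length intensity trace of one tracked particle.

    Frames where the particle was detected carry the fitted amplitude;
    interior gap-closed frames are linearly interpolated; frames outside
    the track are zero.
    """
    trace = np.zeros(n_frames)
    first, last = traj.start_frame, traj.end_frame
    full = np.arange(first, last + 1)
    trace[full] = np.interp(full, traj.frames, traj.intensity)
    return trace


def dwell_time(trace: np.ndarray, frame_interval_s: float,
               threshold_frac: float = 0.5, traj_id: int = -1) -> DwellRecord:
    """Dwell from a background-subtracted fluorescence trace.

    The trace is normalized to its maximum; the dwell is the longest
    contiguous run of frames at or above ``threshold_frac`` times the
    frame interval. A run touching the first or last movie frame is
    censored (the true residence extends beyond the recording).
    """
    trace = np.asarray(trace, dtype=float)
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be strictly positive")
    peak = trace.max(initial=0.0)
    if peak <= 0:
        raise RefusalError("all-zero trace: no particle signal to measure")
    above = trace >= threshold_frac * peak
    best_len, best_start = 0, 0
    run_len, run_start = 0, 0
    for i, flag in enumerate(above):
        if flag:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    censored = best_start == 0 or best_start + best_len == len(trace)
    return DwellRecord(traj_id, best_len * frame_interval_s, censored,
                       best_len, trace)


def dwell_from_trajectories(trajs: list[Trajectory], n_frames: int,
                            frame_interval_s: float,
                            threshold_frac: float = 0.5) -> list[DwellRecord]:
    records = []
    for t in trajs:
        trace = trajectory_trace(t, n_frames)
        records.append(dwell_time(trace, frame_interval_s, threshold_frac,
                                  traj_id=t.id))
    return records


def summarize_dwell(records: list[DwellRecord],
                    condition_label: str = "") -> DwellSummary:
    """Arithmetic mean +/- SD over uncensored records; censored counted apart."""
    if not records:
        raise RefusalError("no dwell records to summarize")
    values = np.array([r.dwell_s for r in records if not r.censored])
    n_cens = sum(r.censored for r in records)
    if len(values) == 0:
        return DwellSummary(condition_label, math.nan, math.nan, 0, n_cens)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return DwellSummary(condition_label, float(values.mean()), sd,
                        len(values), n_cens)


def estimate_dwell_mean(records: list[DwellRecord], frame_interval_s: float,
                        min_frames: int = 2) -> float:
    """Exponential dwell mean corrected for minimum track length and censoring.

    The number of frames K a particle is observed follows a geometric law
    with ratio rho = exp(-Dt/mu); tracks with K < min_frames never enter the
    record (left truncation) and tracks alive at a movie edge are right-
    censored. The geometric MLE with both corrections is rho = S/(S+d),
    where S sums (K - min_frames) over all records and d counts the
    uncensored ones; then mu = -Dt / log(rho).
    """
    ks = np.array([r.n_frames_above for r in records
                   if r.n_frames_above >= min_frames])
    cens = np.array([r.censored for r in records
                     if r.n_frames_above >= min_frames], dtype=bool)
    d = int((~cens).sum())
    if d == 0:
        raise RefusalError("no uncensored records at or above min_frames")
    S = float((ks - min_frames).sum())
    if S <= 0:
        raise RefusalError("all observed dwells at the minimum length; "
                           "mean is not identifiable")
    return -frame_interval_s / math.log(S / (S + d))


def records_to_dataframe(records: list[DwellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.traj_id, r.dwell_s, r.censored, r.n_frames_above) for r in records],
        columns=["id", "dwell_s", "censored", "n_frames_above"])
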