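"""Internalized-fraction quantification from confocal z-stacks.

The internalized fraction of a plasma-membrane protein is the ratio of
background-subtracted fluorescence in the cytoplasm to that in the whole
cell, measured in optical sections 2-3 um below the apical plasma
membrane. Segmentation: Otsu threshold on the maximum projection, closed
and hole-filled, gives the cell footprint; the plasma membrane is a
morphological boundary band of configurable thickness, kept only when it
is actually brighter than the interior (so a fully internalized cell does
not have its cytoplasm edge misread as membrane); the cytoplasm is the
remainder of the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import RefusalError
from .io import ZStack


@dataclass
class InternalizationResult:
    fraction: float
    per_slice_fractions: np.ndarray
    n_slices: int
    cell_mask: np.ndarray
    pm_mask: np.ndarray


def _background_mode(values: np.ndarray) -> float:
    """Mode of integer-like counts; robust to sparse bright structures."""
    v = np.asarray(values).ravel()
    if v.size == 0:
        return 0.0
    v = np.round(v).astype(np.int64)
    v = v[v >= 0]
    if v.size == 0:
        return 0.0
    return float(np.bincount(v).argmax())


def select_analysis_slices(stack: ZStack,
                           depth_range_um: tuple[float, float] = (2.0, 3.0),
                           bg_factor: float = 1.5) -> tuple[np.ndarray, dict]:
    """Slices whose depth below the detected apical surface lies in range.

    The apical surface is the first slice whose mean intensity exceeds the
    stack-wide background mode by ``bg_factor`` (plus one count, so an
    all-zero background cannot trigger). Refuses with depth diagnostics
    when no slice qualifies.
    """
    lo, hi = depth_range_um
    if lo < 0 or hi < lo:
        raise ValueError("depth_range_um must satisfy 0 <= lo <= hi")
    bg = _background_mode(stack.slices)
    means = stack.slices.reshape(stack.n_slices, -1).mean(axis=1)
    thr = bg * bg_factor + 1.0
    bright = np.flatnonzero(means > thr)
    if len(bright) == 0:
        raise RefusalError(
            f"no apical surface: no slice mean exceeds {thr:.2f} "
            f"(background mode {bg:.1f}; slice means {np.round(means, 1)})")
    apical = int(bright[0])
    depths = (np.arange(stack.n_slices) - apical) * stack.z_step_um
    sel = np.flatnonzero((depths >= lo - 1e-9) & (depths <= hi + 1e-9))
    info = {"apical_slice": apical, "background_mode": bg,
            "depths_um": depths, "selected": sel}
    if len(sel) == 0:
        raise RefusalError(
            f"no slice lies {lo}-{hi} um below the apical surface "
            f"(apical slice {apical}, available depths "
            f"{depths.min():.2f} to {depths.max():.2f} um)")
    return stack.slices[sel], info


def segment_cell(stack_or_image, ring_px: int = 8, closing_radius: int = 2,
                 dilate_px: int = 3, membrane_contrast: float = 1.5
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Cell and plasma-membrane masks from a stack or 2D image.

    Otsu on the max projection -> binary closing -> hole fill -> largest
    component -> dilation by ``dilate_px`` (so the faint outer tail of the
    membrane stays inside the cell). The candidate PM is the band within
    ``ring_px`` of the cell boundary; it is accepted as membrane only if
    its median intensity exceeds ``membrane_contrast`` times the interior
    median (above background) — medians, because sparse bright endosomes in
    the band must not masquerade as a membrane. When the test fails the PM
    mask is empty and the whole cell counts as cytoplasm.
    """
    arr = np.asarray(stack_or_image, dtype=float)
    proj = arr.max(axis=0) if arr.ndim == 3 else arr
    if proj.ndim != 2:
        raise ValueError("expected a 2D image or (Z, H, W) stack")
    if np.ptp(proj) == 0:
        raise RefusalError("flat image: nothing to segment")
    mask = proj > threshold_otsu(proj)
    mask = ndi.binary_closing(mask, structure=disk(closing_radius))
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n == 0:
        raise RefusalError("segmentation found no cell")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    cell = labels == (1 + int(np.argmax(sizes)))
    if dilate_px > 0:
        cell = ndi.binary_dilation(cell, structure=disk(dilate_px))

    edt = ndi.distance_transform_edt(cell)
    band = cell & (edt <= ring_px)
    interior = cell & (edt > ring_px)
    bg = _background_mode(proj[~cell])
    # upper quartiles: insensitive both to the dark edges of the band and
    # to sparse bright endosomes in the interior
    band_med = np.percentile(proj[band], 75) - bg if band.any() else 0.0
    interior_med = np.percentile(proj[interior], 75) - bg if interior.any() else 0.0
    if interior.any() and band_med <= membrane_contrast * max(interior_med, 0.0):
        pm = np.zeros_like(cell)    # no membrane enhancement: all cytoplasm
    else:
        pm = band
    return cell, pm


def internalized_fraction(sub: ZStack | np.ndarray, cell_mask: np.ndarray,
                          pm_mask: np.ndarray, pooled: bool = False
                          ) -> InternalizationResult:
    """Cytoplasm / whole-cell intensity ratio over the selected slices.

    Per-slice background (mode of pixels outside the cell) is subtracted
    before summing. By default per-slice ratios are averaged so every
    optical section weighs equally; ``pooled=True`` sums intensities across
    slices first instead.
    """
    slices = sub.slices if isinstance(sub, ZStack) else np.asarray(sub)
    if slices.ndim == 2:
        slices = slices[None]
    cell_mask = np.asarray(cell_mask, dtype=bool)
    pm_mask = np.asarray(pm_mask, dtype=bool)
    if np.any(pm_mask & ~cell_mask):
        raise ValueError("pm_mask must be contained in cell_mask")
    cyto_mask = cell_mask & ~pm_mask

    ratios, cyto_tot, whole_tot = [], 0.0, 0.0
    for sl in slices.astype(float):
        bg = _background_mode(sl[~cell_mask])
        # no clipping: negative noise residuals must cancel positive ones,
        # otherwise the large cytoplasm area accrues a positive floor
        img = sl - bg
        whole = float(img[cell_mask].sum())
        cyto = float(img[cyto_mask].sum())
        cyto_tot += cyto
        whole_tot += whole
        if whole > 0:
            ratios.append(cyto / whole)
    if (whole_tot <= 0) or (not ratios):
        raise RefusalError("whole-cell intensity is zero after background "
                           "subtraction; fraction undefined")
    fraction = (cyto_tot / whole_tot) if pooled else float(np.mean(ratios))
    return InternalizationResult(float(fraction), np.asarray(ratios),
                                 len(ratios), cell_mask, pm_mask)


def measure_internalization(stack: ZStack,
                            depth_range_um: tuple[float, float] = (2.0, 3.0),
                            ring_px: int = 6, pooled: bool = False
                            ) -> InternalizationResult:
    """End-to-end: slice selection, segmentation, fraction."""
    sub, _ = select_analysis_slices(stack, depth_range_um)
    cell, pm = segment_cell(sub, ring_px=ring_px)
    return internalized_fraction(sub, cell, pm, pooled=pooled)
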