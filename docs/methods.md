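# Methods

`pmspt` quantifies plasma-membrane (PM) receptor dynamics from three kinds
of fluorescence microscopy — TIRF single-particle movies, confocal
z-stacks, and FLIM photon-arrival data — and ships a synthetic-data
generator with exact ground truth so every estimator is validated by
parameter recovery rather than against raw data that is not publicly
available. This note records the models, the defaults and why, the
numerical choices, and what the validation does and does not demonstrate.

## Single-particle model

Particles on the membrane are modeled as independent 2D Brownian walkers.
Over a frame interval Δt the per-axis displacement is Normal(0, 2DΔt),
where D is the diffusion coefficient (µm²/s). Membrane residence ("dwell")
is memoryless: lifetimes are Exponential(mean `dwell_mean_s`), and new
particles appear as a Poisson process (`birth_rate_per_frame`), with
continuous birth times within a frame. Particles that step outside the
field are removed and recorded as boundary deaths (simpler truth
bookkeeping than reflection). No photobleaching, blinking, merging or
directed transport is simulated.

Defaults follow the regime reported for PM receptor imaging in plants:
D = 2×10⁻³ µm²/s, dwell mean 2 s, frame interval 0.15 s. The 0.15 s
default is one of two intervals attested for such acquisitions (1.5 s
appears as well); it is a parameter, not an assertion. Pixel size
(0.1 µm/px), PSF width (σ = 1.2 px), photon budget (400 photons/spot,
20 background photons/px, read noise SD 2) are package defaults chosen to
give detection SNR ≈ 9, typical of EM-CCD TIRF at moderate excitation;
none of them is claimed from any specific instrument.

Camera model: expected photon image (Gaussian spots, discretely normalized
to their photon budget, plus uniform background) → Poisson shot noise →
additive Gaussian read noise → clip at 0 → 16-bit quantization. This
matches an EM-CCD qualitatively without modeling multiplication gain.

## Detection and linking

Detection is Laplacian-of-Gaussian band-pass at the PSF scale, local
maxima above a robust threshold, then least-squares 2D Gaussian refinement
(amplitude, subpixel x/y, width, background) in a (2w+1)² window,
w = max(3, round(2σ)). The fits are batched (a vectorized
Levenberg–Marquardt with fixed damping, 20 iterations), which makes the
tens of thousands of fits in a recovery run cheap. Acceptance filters:
fitted width within [0.5, 2.5]·σ_PSF, amplitude within 3× the stamp's data
range, amplitude/noise ≥ the SNR threshold, where noise is 1.4826·MAD of
the high-pass residual. A detection whose fitted width exceeds 1.3·σ_PSF
triggers a two-spot refit (shared PSF width, split along the stamp's
principal axis); the split is accepted only if it decisively lowers the
residual, both amplitudes clear the SNR threshold, and the separation
exceeds 1.5 px. This rescues most particle pairs between ~2 and ~4 px
apart, which a single-Gaussian model would otherwise merge. Detections
within 1 σ_PSF of a brighter one, or within 2 σ_PSF at less than half its
amplitude, are treated as duplicate/shoulder fits and suppressed.

Linking is greedy nearest-neighbour under a distance gate (`max_disp_px`),
with gap closing up to `max_gap_frames` and the gate scaled proportionally
to the gap length. Ties break by distance, then track id, then detection
position, so results do not depend on detection order. This is a
deliberate simplification of full multiple-hypothesis (cost-matrix)
tracking: at the sparse densities single-particle imaging requires
(≲0.005 spots/px²), the downstream statistics are insensitive to linker
sophistication. There is no merge/split handling. Minimum trajectory
length defaults to 5 points — needed for stable per-trajectory MSD fits —
and is lowered to 2 for dwell analysis (see below).

## Diffusion and motion range

Per trajectory, the time-averaged MSD is computed over lags k = 1..max_lag
from all frame pairs exactly k frames apart; by default pairs spanning
unobserved (gap-closed) frames are skipped. D is slope/4 of an OLS line
through the first `n_lags` (default 4) lags; short-lag fitting limits
confinement and noise bias (standard SPT practice), and the intercept
absorbs static localization error. Negative slopes are clamped to D = 0
and flagged rather than dropped, keeping population counts interpretable.
Motion range is the maximum pairwise distance among a trajectory's
positions.

A population of per-trajectory values (D or motion range) is summarized by
Ĝ, the mean of a single Gaussian fitted to its histogram
(Freedman–Diaconis bins by default; the fit refuses degenerate input and
peaks escaping the histogram support, so multimodality surfaces instead of
being averaged away). Trajectories are pooled across the field of view;
per-cell averaging can be done by calling the population fit per subset.

## Dwell times

A tracked particle's trace (fitted amplitude per frame, linearly
interpolated across gap-closed frames) is normalized to its maximum; dwell
is the longest contiguous run at or above half-max (threshold
configurable) times Δt. Runs touching the first or last movie frame are
right-censored: excluded from the plain mean and counted separately. The
kymograph module renders position-along-a-line versus time images
(bilinear sampling, averaged over a perpendicular width) as the visual
counterpart of the same residence events.

The plain arithmetic mean of observed dwells is a biased estimator of an
exponential dwell mean: tracks shorter than the tracker's minimum length m
are unobservable, and by memorylessness the observable mean is
(m + ρ/(1−ρ))·Δt with ρ = exp(−Δt/µ) — about +m·Δt. `estimate_dwell_mean`
is the exact correction: the observed frame count K is geometric, left-
truncated at m and right-censored at the movie edges, and its MLE is
ρ̂ = S/(S+d) with S = Σ(Kᵢ−m) over all records and d the number of
uncensored ones, giving µ̂ = −Δt/ln ρ̂. Summaries report both the plain
mean±SD and the corrected mean; recovery is asserted on the corrected one.

## Internalization

The internalized fraction of a PM protein is the background-subtracted
cytoplasm / whole-cell intensity ratio in optical sections 2–3 µm below
the apical surface (detected as the first slice whose mean exceeds the
stack background mode by a configurable factor). Segmentation: Otsu on the
max projection → closing → hole fill → largest component → dilation by
3 px so the faint outer tail of the membrane stays inside the cell mask.
The candidate PM is the band within `ring_px` (default 8 px) of the cell
boundary; it counts as membrane only when its upper-quartile intensity
exceeds 1.5× the interior's (above background). Quartiles are robust both
to sparse bright endosomes wandering into the band and to the band's dark
outer edge; without this rule a fully internalized cell — which has no
membrane signal at all — would have the edge of its cytoplasmic signal
misread as PM, and any erosion-based ring would misclassify ~20% of the
signal. Background is the mode of non-cell pixels per slice, subtracted
without clipping (clipping negative residuals to zero accrues a positive
floor over the large cytoplasm area). Per-slice ratios are averaged so
each optical section weighs equally (pooling is available).

The confocal phantom is a vertical cylinder: every lateral slice carries
the same membrane annulus with a uniform cytoplasmic pool plus puncta
inside it, with the fraction `internal_fraction` of each slice's photon
budget allocated to the cytoplasm. A cylinder (rather than a capped
sphere) makes the cytoplasm/whole-cell ratio equal the set fraction
exactly, per slice and over the volume, so recovery error is attributable
to the measurement, not the phantom. Ground truth records the allocated
(pre-blur) fraction — where the protein is, not where the PSF puts its
photons — plus the geometric masks.

## FLIM and FRET

Each pixel holds a histogram of photon arrival times within a window W.
For a monoexponential decay truncated to W the mean arrival time is
m(τ) = τ − W/(e^{W/τ} − 1); the ML lifetime estimate inverts this equation
(Brent's method) on the empirical mean. No instrument-response
deconvolution is attempted (none is available), but the truncation is
handled analytically — the naive mean-arrival estimate is biased low, and
a log-linear least-squares fit is kept only as a cross-check. Pixels below
`min_photons` (default 100) are flagged unfit; ROI lifetimes are
photon-weighted means over fit pixels. Lifetime maps render on a fixed
absolute scale, navy at 2.1 ns to red at 2.7 ns, clamped outside, unfit
pixels black.

FRET efficiency from donor-only (τ_D) and donor+acceptor (τ_DA) lifetimes
is E = (1 − τ_DA/τ_D)·100%. Negative values (τ_DA > τ_D) are reported and
flagged, not clipped. Because E is a ratio, averaging per ROI pair and
then pooling differs slightly from computing E on pooled mean lifetimes;
`fret_from_rois` reports both. On the donor/DA design lifetimes
2.53/2.36 ns the formula gives 6.72%.

## Statistics

Condition comparisons use Welch's unequal-variance t-test (group variances
routinely differ between treatment arms; with equal variances it reduces
to the pooled Student test). With more than two groups, pairwise p-values
are Holm-corrected. Duncan's multiple-range procedure is deliberately not
implemented — it is deprecated and underspecified without error-rate
details — and Welch+Holm letters stand in for it. Summaries are mean ± SD
with n; single-replicate conditions are summarized but never tested.

## Validation: problem sizes and what passing shows

The recovery experiments (in `pmspt.validation`, run by both the test
suite and `scripts/acceptance.py`) use problem sizes chosen to give the
estimators meaningful statistics on a single CPU in a few minutes:

- Diffusion: 560 particles, 150 frames, 384² px, effectively immortal
  dwell so trajectories are long and per-trajectory D̂ is tight. Ĝ of D̂
  recovers 2×10⁻³ µm²/s within a few percent, both on true positions and
  through detection+tracking.
- Dwell: ~1400–1500 uncensored tracks per condition (760 frames, 160² px);
  corrected means recover 2.0 s and 1.5 s within 10% with ordering
  preserved.
- Detection: 120 particles in 256² px (0.0018 spots/px² ≈ 0.18 spots/µm²),
  the sparse labeling regime single-particle imaging requires; precision
  and recall ≥ 0.95 at 1 px matching. Both degrade gracefully toward the
  ~2-PSF resolution limit as density rises.
- Internalization: fractions {0, 0.1, 0.25, 0.5, 1} recovered within
  ±0.02, strictly monotone, with fully automatic segmentation.
- FLIM: lifetimes {2.1, 2.36, 2.53, 2.7} ns at 10⁴ photons/px recovered
  within 2% (in practice ≪1%).

Passing these shows the estimators are correct and well-calibrated **for
the generative model above**. Real movies additionally contain
photobleaching, blinking fluorophores, uneven illumination, membrane
topography, motion blur within exposures, and non-Brownian motion modes —
none of which the simulator emulates. Recovery here is therefore a
necessary, not sufficient, condition for accuracy on real data.

## Degenerate inputs and refusals

Operations refuse rather than guess: empty traces, single-point
trajectories, histograms with zero spread or fewer than 50 values,
ROIs without fit pixels, stacks without a detectable apical surface or
without slices in the requested depth range, whole-cell intensity ≤ 0
after background subtraction, and non-positive lifetimes all raise
`RefusalError`/`FitError` with a diagnostic message.

## Known limitations

- The linker is greedy; at densities approaching 0.01 spots/px² identity
  swaps and merges will bias dwell times down and D up.
- The dwell correction assumes a single exponential population; mixtures
  are not modeled.
- Lifetime fitting is monoexponential with no IRF; bound/free fractions
  (bi-exponential) and phasor analysis are out of scope.
- The internalization phantom's membrane/cytoplasm contrast rule assumes
  endosomes occupy a minority of the boundary band; cells whose membrane
  is dimmer than ~1.5× the cytoplasm will be treated as fully cytoplasmic.
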