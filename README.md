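# pmspt — plasma-membrane single-particle imaging analysis

`pmspt` is a Python library for quantifying the dynamics of plasma-membrane
(PM) receptors from fluorescence microscopy, written for the workflows used
to study receptor endocytosis and lateral mobility (e.g. the Arabidopsis
7TM regulator AtRGS1 and its Gα partner AtGPA1). It covers four readouts:

- **Single-particle tracking and diffusion** from TIRF movies: spot
  detection with subpixel Gaussian refinement, nearest-neighbour linking
  with gap closing, per-trajectory mean-square displacement (MSD), the
  diffusion coefficient *D* from the MSD-*t* slope (MSD = 4*D*t), the
  motion range, and the population summary Ĝ — the peak of a Gaussian
  fitted to the histogram of a per-trajectory statistic.
- **Membrane dwell times**: kymographs along sampled lines, per-particle
  residence from normalized fluorescence traces (longest half-max run),
  censoring-aware summaries, and an exact truncation-corrected exponential
  mean estimator.
- **Internalization** from confocal z-stacks: the background-subtracted
  cytoplasm / whole-cell intensity ratio in sections 2–3 µm below the
  apical membrane, with automatic cell/membrane segmentation.
- **FLIM-FRET**: per-pixel monoexponential lifetime fitting by the
  truncated-window maximum-likelihood equation, photon-weighted ROI
  averages, fixed-scale (2.1–2.7 ns, navy→red) lifetime maps, and FRET
  efficiency E = (1 − τ_DA/τ_D)·100%.

Because raw single-particle microscopy of this kind is rarely deposited,
the package also ships a **synthetic-microscopy simulator**
(`pmspt.simulate`) that generates TIRF movies (2D Brownian walkers with
exponential membrane dwell, Gaussian PSF, Poisson + read noise), confocal
cell phantoms with a controllable internalized fraction, and TCSPC decay
histograms — each with exact ground truth. Every estimator in the package
is validated by recovering the simulator's hidden parameters.

## A worked example

`examples/01_track_and_diffusion.py` simulates a movie of 250 particles
diffusing at D = 2×10⁻³ µm²/s (0.15 s frames, 0.1 µm pixels), tracks them,
and recovers the population peak:

```
tracked trajectories : 280
true D               : 2.00e-03 um^2/s
G-hat of D           : 2.04e-03 um^2/s (sigma 4.8e-04, n 280)
G-hat of motion range: 0.43 um
median fit r^2       : 1.00
```

Ĝ of the per-trajectory diffusion coefficients lands within 2% of the true
value, and the motion-range peak (~0.4 µm) is how far a particle wanders
during its trajectory in this regime. `examples/05_two_condition_run.py`
runs a full two-condition comparison (control-like vs treated-like, where
the treatment raises D and shortens dwell):

```
CK   : 416 tracks, mean D 2.02e-03 um^2/s, dwell 2.62 s (corrected 2.05)
MeJA : 354 tracks, mean D 3.13e-03 um^2/s, dwell 2.07 s (corrected 1.43)
diffusion Welch test CK vs MeJA: p = 8.83e-11
dwell Welch test CK vs MeJA: p = 4.82e-06
```

Both true means (2.0 s vs 1.5 s dwell; 2 vs 3 ×10⁻³ µm²/s) are recovered
by the corrected estimators and separate decisively under Welch's t-test.
The other examples cover dwell measurement, internalization (a phantom
with 23% internalized signal is read back as 0.237) and FLIM-FRET (donor
2.53 ns vs donor+acceptor 2.36 ns gives E = 6.72%).

A thin CLI wraps the common shell steps:

```bash
pmspt simulate tirf --seed 1 --out demo/
pmspt track --in demo/movie.tif --snr 5 --max-disp 2.5 --out demo/traj.csv
pmspt run --config examples/config_demo.yaml
```

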