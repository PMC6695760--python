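"""Simulate a TIRF movie, track the particles, recover the diffusion peak.

Membrane particles diffuse at D = 2e-3 um^2/s and are imaged every 0.15 s.
We detect and link them, fit each trajectory's MSD-t line (D = slope/4),
and summarize the population by the Gaussian histogram peak G-hat.
"""

import numpy as np

from pmspt import (TirfSimParams, analyze_trajectories, fit_population_peak,
                   simulate_tirf_movie, track_movie)

params = TirfSimParams(field_size_px=(256, 256), n_frames=120,
                       diffusion_um2_s=2e-3, dwell_mean_s=1e6,
                       birth_rate_per_frame=0.0, n_initial=250, seed=42)
stack, truth = simulate_tirf_movie(params)

trajs = track_movie(stack, max_disp_px=2.0, min_length=20)
per_traj = analyze_trajectories(trajs, params.frame_interval_s, n_lags=4)
pop = fit_population_peak(per_traj["D_um2_s"], "diffusion_coefficient")
rng_pop = fit_population_peak(per_traj["motion_range_um"], "motion_range")

print(f"tracked trajectories : {len(trajs)}")
print(f"true D               : {truth.true_diffusion_um2_s:.2e} um^2/s")
print(f"G-hat of D           : {pop.peak:.2e} um^2/s "
      f"(sigma {pop.width_sigma:.1e}, n {pop.n_values})")
print(f"G-hat of motion range: {rng_pop.peak:.2f} um")
print(f"median fit r^2       : {np.median(per_traj['r2']):.2f}")
print()
print("G-hat of D should sit within a few percent of the true coefficient;")
print("the motion-range peak reflects how far a particle wanders in a")
print("trajectory lifetime (~0.4-0.5 um in this regime).")
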