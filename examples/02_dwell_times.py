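"""Measure membrane dwell times from tracked particles.

Particles are born continuously and live Exponential(2.0 s) on the
membrane. The plain mean of observed dwells overestimates the true mean
(tracks below the minimum length are unobservable); the truncation- and
censoring-corrected geometric MLE recovers it.
"""

from pmspt import (TirfSimParams, dwell_from_trajectories,
                   estimate_dwell_mean, simulate_tirf_movie, summarize_dwell,
                   track_movie)

params = TirfSimParams(field_size_px=(128, 128), n_frames=400,
                       diffusion_um2_s=2e-3, dwell_mean_s=2.0,
                       birth_rate_per_frame=1.0, seed=7)
stack, truth = simulate_tirf_movie(params)

trajs = track_movie(stack, max_disp_px=2.5, max_gap_frames=2, min_length=2)
records = dwell_from_trajectories(trajs, stack.n_frames,
                                  stack.frame_interval_s)
summary = summarize_dwell(records, "demo")
corrected = estimate_dwell_mean(records, stack.frame_interval_s, min_frames=2)

print(f"true dwell mean      : {truth.true_dwell_mean_s:.2f} s")
print(f"uncensored tracks    : {summary.n} (+{summary.n_censored} censored)")
print(f"plain mean +/- SD    : {summary.mean_s:.2f} +/- {summary.sd_s:.2f} s")
print(f"corrected mean (MLE) : {corrected:.2f} s")
print()
print("The plain mean carries the +min_length*frame_interval acquisition")
print("bias; the corrected estimator should land near the true 2.0 s.")
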