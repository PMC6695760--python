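"""A reproducible two-condition end-to-end run with statistics.

Control-like (CK: D = 2e-3 um^2/s, dwell 2.0 s) versus treated-like
(MeJA: D = 3e-3, dwell 1.5 s) movies are simulated, tracked and analyzed;
conditions are compared with Welch's t-test and a manifest of checksums
makes the run verifiably reproducible.
"""

import json
import tempfile
from pathlib import Path

from pmspt import RunConfig, run_pipeline

tirf = {"field_size_px": [128, 128], "n_frames": 400,
        "diffusion_um2_s": 2e-3, "dwell_mean_s": 2.0,
        "birth_rate_per_frame": 1.5}
config = RunConfig(
    seed=21,
    conditions=[
        {"label": "CK", "tirf": tirf},
        {"label": "MeJA", "tirf": dict(tirf, diffusion_um2_s=3e-3,
                                       dwell_mean_s=1.5)},
    ],
    tracking={"min_length": 5, "max_disp_px": 2.5, "max_gap_frames": 2})

with tempfile.TemporaryDirectory() as out:
    manifest = run_pipeline(config, out)
    summary = json.loads(Path(out, "summary.json").read_text())
    comparison = json.loads(Path(out, "comparison.json").read_text())

d_means = {s["label"]: s for s in comparison["diffusion"]["summaries"]}
for label, s in summary.items():
    dw = s["dwell"]
    d = d_means[label]
    print(f"{label:5s}: {s['n_trajectories']:3d} tracks, "
          f"mean D {d['mean']:.2e} um^2/s, "
          f"dwell {dw['mean_s']:.2f} s (corrected {dw['corrected_mean_s']:.2f})")
for stat in ("diffusion", "dwell"):
    test = comparison[stat]["tests"][0]
    print(f"{stat} Welch test {test['label_a']} vs {test['label_b']}: "
          f"p = {test['p_value']:.2e}")
print(f"manifest files: {len(manifest['checksums'])} "
      f"(re-running with seed {manifest['seed']} reproduces every checksum)")
print()
print("Treated-like particles diffuse faster and leave the membrane sooner;")
print("at ~10-frame track lengths the per-track D estimates are noisy, so")
print("condition contrasts use their means with Welch's t-test.")
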