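"""Fit FLIM lifetimes and compute FRET efficiency.

Donor-only pixels decay with tau = 2.53 ns; donor+acceptor pixels with
tau = 2.36 ns (energy transfer shortens the donor's excited-state
lifetime). We fit per-pixel lifetimes by the truncated-exponential MLE,
average over an ROI, and report E = (1 - tau_DA/tau_D) * 100%.
"""

import numpy as np

from pmspt import (FlimSimParams, fit_lifetime_map, fret_efficiency,
                   render_lifetime_map, roi_lifetime, simulate_flim)

roi = np.ones((24, 24), dtype=bool)
taus = {}
for label, tau in (("donor", 2.53), ("donor+acceptor", 2.36)):
    params = FlimSimParams(lifetime_map_ns=np.full((24, 24), tau),
                           photons_per_pixel=1e4, seed=13)
    lt_map = fit_lifetime_map(simulate_flim(params))
    mean, sd, n = roi_lifetime(lt_map, roi)
    taus[label] = mean
    print(f"{label:15s}: tau = {mean:.3f} +/- {sd:.3f} ns  ({n} pixels)")
    rgb = render_lifetime_map(lt_map)     # navy(2.1 ns) -> red(2.7 ns)

eff = fret_efficiency(taus["donor"], taus["donor+acceptor"])
print(f"FRET efficiency: {eff:.2f} %")
print()
print("With these lifetimes the formula gives ~6.7%: the donor and the")
print("acceptor-tagged partner are close enough for energy transfer.")
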