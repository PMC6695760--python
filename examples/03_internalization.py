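"""Quantify receptor internalization from a confocal z-stack.

A cell phantom puts 23% of its signal in the cytoplasm (the level seen
after 8 h of stimulus in receptor-endocytosis experiments). The pipeline
picks slices 2-3 um below the apical surface, segments the cell and its
membrane ring, and reports the cytoplasm/whole-cell intensity ratio.
"""

from pmspt import (ConfocalSimParams, measure_internalization,
                   simulate_confocal_stack)

params = ConfocalSimParams(internal_fraction=0.23, seed=11)
stack, truth = simulate_confocal_stack(params)
result = measure_internalization(stack, depth_range_um=(2.0, 3.0))

print(f"set internal fraction     : {params.internal_fraction:.2f}")
print(f"truth (noiseless)         : {truth.internal_fraction_true:.3f}")
print(f"measured fraction         : {result.fraction:.3f}")
print(f"per-slice fractions       : "
      + ", ".join(f"{r:.3f}" for r in result.per_slice_fractions))
print()
print("Measured vs set fraction should agree within ~0.02; the per-slice")
print("values show the section-to-section spread the average smooths over.")
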