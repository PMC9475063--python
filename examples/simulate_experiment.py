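"""Simulate a blocked audio-visual distance-coincidence experiment.

Builds the standard design (visual targets at 1.5/3.0/4.5 m, 11 auditory
distances per block, 30 trials per stimulus, 11 subjects) and a correlated
log-normal observer, then prints the pooled proportion-coincident curve for
the 3 m block.
"""

import numpy as np

import distcapture as dc

design = dc.default_design()
observer = dc.ObserverParams(seed=1)

print(f"visual blocks: {design.visual_targets}")
print(f"measurement grid: {len(design.measurement_grid)} distances, "
      f"{design.measurement_grid[0]}-{design.measurement_grid[-1]} m")

responses = dc.simulate_coincidence_responses(design, observer)
pc = dc.proportion_coincident(responses, pooled=True)
block = pc[pc["visual_m"] == 3.0]
print(f"\n{len(responses)} trials total; pooled pc for the 3 m visual target "
      f"({block['n_trials'].iloc[0]} trials/point):")
for _, row in block.iterrows():
    print(f"  auditory {row.auditory_m:4.2f} m  pc = {row.pc:.3f}")
print("\npc peaks near (slightly beyond) the visual target and falls off with "
      "audio-visual separation; the far side falls more slowly because the "
      "observer compares distances on a log scale.")
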