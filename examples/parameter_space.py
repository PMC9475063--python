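"""Explore the model parameter space: what k_aud and r each control.

Sweeps the free auditory constant k_aud (with r = 0) and the inter-modal
correlation r (with k_aud = 1) for the log-scale model at the 3 m visual
target, and demonstrates the predicted near/far capture asymmetry.
"""

import numpy as np

import distcapture as dc

unit = dc.PowerFit(k=1.0, a=1.0, r_squared=1.0)
spec = dc.ModelSpec(variant="M3", aud_fit=unit, vis_fit=unit)
grid = np.linspace(1.0, 6.0, 501)

print("sweeping k_aud (r = 0): position of the d' minimum")
for k, curve in dc.parameter_sweep(spec, 3.0, grid, "k_aud", [0.5, 1.0, 2.0]).items():
    print(f"  k_aud = {k}: minimum at {grid[np.argmin(curve)]:.2f} m")
print("k_aud slides the point of strongest capture along the distance axis "
      "(minimum at x = 3/k_aud for matched unit power laws).")

print("\nsweeping r (k_aud = 1): sharpness at +/-1 m from the target")
for r, curve in dc.parameter_sweep(spec, 3.0, grid, "r", [0.0, 0.5, 0.9]).items():
    at2 = np.interp(2.0, grid, curve)
    at4 = np.interp(4.0, grid, curve)
    print(f"  r = {r}: d'(2 m) = {at2:.2f}, d'(4 m) = {at4:.2f}")
print("larger r removes shared noise from the comparison, sharpening the "
      "coincidence function; d'(2 m) > d'(4 m) is the proximity-image "
      "asymmetry — equal linear offsets are larger log ratios on the near side.")
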