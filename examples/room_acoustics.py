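"""Distance dependence of acoustic cues and the room's critical distance.

Builds a synthetic cue table for a point source in a diffuse reverberant
field (direct energy ~ 1/x**2, constant reverberant energy), fits dB-per-
doubling functions to level and direct-to-reverberant ratio (DRR), and
solves the DRR fit for the critical distance.
"""

import distcapture as dc

table = dc.synthetic_cue_table(critical_distance_m=2.38, level_at_1m_db=60.0,
                               level_slope_db=-4.0)
level = dc.fit_db_per_doubling(table["distance_m"], table["level_db"])
drr = dc.fit_db_per_doubling(table["distance_m"], table["drr_db"])
cd = dc.critical_distance(drr)

print(f"level: {level.slope_db_per_doubling:.2f} dB per doubling "
      f"(R^2 = {level.r_squared:.3f})")
print(f"DRR:   {drr.slope_db_per_doubling:.2f} dB per doubling "
      f"(R^2 = {drr.r_squared:.3f})")
print(f"critical distance: {cd.distance_m:.2f} m"
      + (" (extrapolated)" if cd.extrapolated else ""))
print("\nthe critical distance is where direct and reverberant energies are "
      "equal (DRR = 0 dB); an inverse-square direct field gives exactly "
      "-6.02 dB DRR per doubling.")
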