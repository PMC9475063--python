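"""Empirical d' curves with bootstrap CIs, and coincidence-model fits.

Computes d' = z(pc_max) - z(pc) per block from simulated responses, attaches
95% subject-bootstrap confidence intervals, then fits the three coincidence
models (M1 linear/constant variance, M2 linear/scaled variance, M3
logarithmic) with two free parameters (k_aud, r) and compares RMS errors.
"""

import distcapture as dc

design = dc.default_design()
observer = dc.ObserverParams(seed=1)
responses = dc.simulate_coincidence_responses(design, observer)
judgments = dc.simulate_absolute_judgments(design, observer)

curves = dc.bootstrap_ci(responses, B=1000, seed=1)
c = curves[3.0]
print("pooled d' for the 3 m visual target (95% bootstrap CI, n=11 subjects):")
for d, dp, lo, hi in zip(c.auditory_m, c.dprime, c.ci_low, c.ci_high):
    print(f"  {d:4.2f} m  d' = {dp:5.2f}  [{lo:5.2f}, {hi:5.2f}]")
print(f"strongest capture (d' = 0) at {c.ref_distance_m} m, pc_max = {c.pc_max:.3f}")

power = dc.fit_power_judgments(judgments)
aud = power[power["modality"] == "aud"].iloc[0]
vis = power[power["modality"] == "vis"].iloc[0]
base = dc.ModelSpec(
    variant="M3",
    aud_fit=dc.PowerFit(aud.k, aud.a, aud.r_squared, "aud"),
    vis_fit=dc.PowerFit(vis.k, vis.a, vis.r_squared, "vis"),
)
table = dc.compare_models(curves, base, n_params=2)
print("\n2-parameter fits (free: k_aud, r); RMS error in d' units:")
for _, row in table.iterrows():
    print(f"  visual {row.visual_m} m  {row.model}: rms = {row.rms_error:.3f} "
          f"(k_aud = {row.k_aud:.2f}, r = {row.r:.2f})")
print("\nlower RMS = better fit; the log-scale model (M3) matches the "
      "asymmetric fall-off that the linear models miss.")
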