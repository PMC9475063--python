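"""Run the whole analysis end to end into a run directory.

simulate -> power fits -> d' (+ bootstrap) -> model fits -> comparison.
Re-running with the same config and seed reproduces byte-identical outputs.
"""

import pandas as pd

import distcapture as dc

config = dc.RunConfig(seed=1, bootstrap_B=500, n_params=(2,),
                      out_dir="scratch/example_run")
out = dc.run_pipeline(config)

print(f"run directory: {out}")
print("outputs:", ", ".join(sorted(p.name for p in out.glob('*.csv'))))
comparison = pd.read_csv(out / "comparison.csv")
print("\nmodel comparison (pooled, 2-parameter, RMS error in d' units):")
print(comparison.pivot(index="visual_m", columns="model", values="rms_error").round(3))
print("\nmanifest.json records the config hash and seed; identical "
      "config + seed => identical CSVs.")
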