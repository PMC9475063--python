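# distcapture

Probabilistic modelling of **visual capture of sound-source distance** (the
ventriloquist effect in depth). When a plausible visual target accompanies a
sound, the sound tends to be localized to the visual target's distance — and
the capture is *asymmetric*: sources farther than the visual target are
captured more strongly than sources nearer by the same linear offset (the
"proximity-image effect"). `distcapture` provides the full analysis chain
needed to study this with yes/no coincidence judgments:

* a **synthetic observer** that simulates blocked coincidence experiments and
  absolute distance judgments from a correlated log-normal percept model;
* **psychometrics**: proportion-coincident curves, the empirical mismatch
  statistic `d' = z(pc_max) − z(pc)`, and subject-level bootstrap CIs;
* **distance scaling**: Stevens power-function fits `y = k·x^a` of judged vs
  physical distance (log-space OLS, geometric-mean aggregation);
* **coincidence models** M1–M3 based on the signal-detection sensitivity
  index between the auditory and visual percept distributions,

  `d' = |μ_aud − μ_vis| / sqrt(σ_aud² + σ_vis² − 2·r·σ_aud·σ_vis)`,

  with power-law means and multiplicative variability factors
  (10^0.23 auditory, 10^0.15 visual): **M1** linear scale/constant variance,
  **M2** linear scale/scaled variance, **M3** logarithmic scale (normal in
  log-distance, log-normal in linear distance);
* **model fitting**: bound-constrained nonlinear least squares with 1, 2 or 3
  free parameters (`k_aud`, `r ∈ [0,1]`, auditory variability factor),
  multi-start, compared by RMS error in d' units;
* **room cues**: dB-per-doubling fits of level and direct-to-reverberant
  ratio and the room's critical distance.

Intended users: auditory/multisensory psychophysicists who want a tested,
reproducible reference implementation of this analysis, and anyone needing a
generative observer model to design or power similar experiments.

## Worked example

```python
import distcapture as dc

design   = dc.default_design()                 # 1.5/3.0/4.5 m blocks, 11 subjects
observer = dc.ObserverParams(seed=1)           # compressive, noisy audition
responses = dc.simulate_coincidence_responses(design, observer)
curve = dc.bootstrap_ci(responses, B=1000, seed=1)[3.0]
for d, dp in zip(curve.auditory_m, curve.dprime):
    print(f"{d:4.2f} m  d' = {dp:5.2f}")
```

prints (abridged) for the 3 m visual target:

```
1.75 m  d' =  1.16
2.50 m  d' =  0.73
3.00 m  d' =  0.11
4.00 m  d' =  0.00
4.25 m  d' =  0.00
```

d' = 0 marks the distance of strongest capture — here ~4 m, *beyond* the
visual target, because the simulated observer underestimates auditory
distance (k=1.32, a=0.54); the near side rises much faster than the far
side, which is the proximity-image asymmetry. Fitting the three models to
the same run (`examples/dprime_models.py`) gives pooled 2-parameter RMS
errors at 3 m of M1 = 0.115, M2 = 0.114, M3 = 0.102 d' units, with the
log-scale model fitting best at 3.0 and 4.5 m.

Each script in `examples/` is a short narrative of one capability:
simulation, power-law scaling, d' + model comparison, parameter-space
exploration, room acoustics, and the end-to-end pipeline
(`dc.run_pipeline(dc.RunConfig(...))`, which writes CSVs and a manifest and
is byte-reproducible under a fixed seed).

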