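# Methods

## The generative observer

Perceived distance in each modality is modelled as log-normal around a
power-law mean: a target at physical distance `x` produces a percept
`exp(N(ln(k·x^a), s))`. On a coincidence trial the auditory and visual log
percepts `(A, V)` are drawn jointly bivariate-normal with correlation `r`,
and the observer answers "coincident" when `|A − V| ≤ c` (a fixed symmetric
criterion in log-distance units). The difference `D = A − V` is normal with
mean `m_aud − m_vis` and SD `s_diff = sqrt(s_aud² + s_vis² − 2·r·s_aud·s_vis)`,
so the probability of a coincident response has the closed form
`pc = Φ((c − μ_D)/s_diff) − Φ((−c − μ_D)/s_diff)` (`predict_pc`), which
serves as the independent oracle for the simulator in the test suite.

Defaults (units: k in m^(1−a), s and c dimensionless log-units):

| parameter | default | why |
|---|---|---|
| `k_aud`, `a_aud` | 1.32, 0.54 | meta-analytic average auditory distance function: compressive, underestimates beyond ~1.6 m |
| `k_vis`, `a_vis` | 1.0, 0.98 | visual distance perception is nearly veridical |
| `s_aud`, `s_vis` | ln(10^0.23), ln(10^0.15) | large-sample multiplicative variability factors of judged distance |
| `r` | 0.8 | concurrent bimodal presentation shares front-end noise; high correlation produces the sharp coincidence functions typical of pooled data |
| `criterion_c` | 0.5 | acceptance ratio ≈ ×1.65; yields pc_max ≈ 0.87 at matched percepts, a realistic ceiling |

The standard design has visual blocks at 1.5/3.0/4.5 m with 11-point
auditory grids in 0.25 m steps centred on the visual target and shifted
inward to stay within the measured 1–5 m range (so the 4.5 m block tops out
at 5 m), 30 trials per stimulus, 11 subjects, auditory absolute judgments at
1–5 m in 0.5 m steps and visual at 1/2/3 m. Every (subject, block) pair gets
an independent, deterministically derived RNG substream from one root seed,
so subject subsets reproduce exactly. Distances are metres throughout.

What the generator does *not* emulate: lapses and response bias, learning or
criterion drift across blocks, subject heterogeneity in (k, a, s, r), and
any front-end acoustics (a real room's cue strength enters only through the
abstract percept noise). Passing tests therefore show that the analysis
chain is correct for an idealised stationary observer, not that real
listeners satisfy the model.

## Empirical d'

Per block, the proportion coincident `pc` is computed per auditory distance
(pooled over subjects or per subject) and converted to
`d' = z(pc_max) − z(pc)`. Proportions are clamped to
`[1/(2n), 1 − 1/(2n)]` (n = trials in the cell) before the z-transform so
empty/full cells stay finite; with n = 330 the attainable ceiling is
`z(1 − 1/660) − z(1/660) ≈ 5.9`. Ties for `pc_max` resolve to the distance
closest to the visual target (then the smaller distance) — the most
plausible capture point. Confidence intervals are percentile bootstrap over
subjects (B = 1000 by default, trials within a subject kept intact),
matching an n = 11 between-subject design.

**Known property — undercoverage.** Because the reference `z(pc_max)` is the
maximum over noisy cells, the empirical curve is biased slightly upward near
its reference, and the subject-percentile interval inherits that bias: in a
200-replicate simulation at generator defaults the nominal 95% band covers
the generating-model d' only ~83% of the time. The test suite freezes this
measured behaviour; CI users should treat the bands as descriptive.

## Coincidence models

All variants feed percept means/SDs into the sensitivity index
`d' = |μ_aud − μ_vis| / sqrt(σ_aud² + σ_vis² − 2·r·σ_aud·σ_vis)`; means come
from the power-law fits to absolute judgments, with `k_aud` free (vision may
anchor the auditory scale under bimodal conditions).

* **M1** (linear, constant variance): σ per modality frozen at
  `factor × k·x^a` evaluated at the 3 m reference distance.
* **M2** (linear, scaled variance): σ = `factor × k·x^a` at each target's own
  distance (auditory over 0 < x < 10 m).
* **M3** (logarithmic): percepts are normal in log-distance with means
  `ln(k·x^a)` and SDs `ln(factor)`.

For M3 the index is evaluated **on the log scale by default**: there the two
distributions are exactly normal, the index is exact, and the model produces
clean log-ratio symmetry — equal *ratios* of auditory to visual distance give
equal d', hence on the linear axis d'(v − Δ) > d'(v + Δ) for every offset
0 < Δ < v. This is the package's own design choice for representing the
logarithmic model. An alternative linear-space representation converts
(m, s) to log-normal moments (`mu = exp(m + s²/2)`,
`σ² = (exp(s²) − 1)·exp(2m + s²)`) and feeds those to the index
(`m3_space="linear"`); that approximation inflates means by `exp(s²/2)`,
shifting the predicted minimum to ≈ 0.92·v for matched power laws and
reversing the near/far asymmetry for small offsets, so it is not the
default. A `printed_formula_mode` additionally swaps the moment mean for the
non-standard `exp(m + s²)` for comparison with legacy formulations; the SD
expression is the same either way.

Degenerate configurations (difference variance ≤ 0, e.g. r = 1 with equal
SDs) raise an error rather than returning infinities.

## Fitting and comparison

Fits are per visual-target block (no sharing across blocks), minimising
unweighted squared error between observed and predicted d' with
`scipy.optimize.least_squares` under bounds `k_aud ∈ [0.05, 20]`,
`r ∈ [0, 1]`, variability factor ∈ (1, 10]. The objective is non-convex in
`k_aud`, so every fit runs a deterministic multi-start grid
(k ∈ {0.5, 1, 2} × r ∈ {0, 0.5, 0.9} × factor ∈ {1.3, 1.7, 2.5} as
applicable) with tolerances 1e-10 and ≤ 500 evaluations per start; the best
optimum is kept and `converged` flags whether any start terminated cleanly.
Model comparison reports RMS error in d' units; per-subject analyses add the
mean ± SE of RMS across subjects per model × distance. Best RMS is
non-increasing in the number of free parameters on any fixed dataset (nested
parameterisations; verified to 1e-8).

**Known property — r is attenuated.** The empirical statistic
`z(pc_max) − z(pc)` is a compressed, offset transform of the underlying
`|μ_D|/s_diff` (exactly linear only in the single-tail regime away from the
minimum). Least-squares fitting of the exact index to the z-based curve
therefore inflates the fitted difference SD, which k_aud absorbs not at all
(it is pinned by the minimum's location) but r absorbs fully: in a
100-replicate recovery study at the standard design scale (11 × 30 trials,
1.5 m block, true power laws supplied) `k_aud` recovers essentially
perfectly (mean 1.30 vs true 1.32; 100% within ±0.15) while fitted `r`
centres on 0.57 vs true 0.8 (~60% within ±0.25). Fitted correlations from
this analysis style should be read as lower bounds on percept correlation.
The recovery study uses the 1.5 m block because, at the default observer,
the perceived-match point (~1.25 m) lies inside that block's grid; at 3 m it
falls at the grid edge and k_aud would be weakly identified.

## Room cues

Cue tables (level and DRR vs distance) are fitted by OLS against
log2(distance), giving dB-per-doubling slopes; the critical distance solves
the DRR fit for 0 dB and is flagged when it lies outside the fitted range.
The bundled synthetic table is an inverse-square direct field over a
constant diffuse field, so its DRR slope is exactly −20·log10(2) ≈ −6.02 dB
per doubling and the crossing is placed by construction (default 2.38 m).

## Problem sizes and determinism

Simulation-based tests use single-CPU-friendly sizes chosen once: 1e5
trials/cell for simulator-vs-closed-form checks (3 binomial SEs), 100
replicates for parameter recovery, 200 outer × 2000 bootstrap replicates for
coverage. All randomness flows from explicit integer seeds; identical
config + seed reproduces byte-identical pipeline outputs, recorded in each
run's manifest (config hash excludes the output path).
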