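# Methods

## The measurement model

An ion-selective electrode (ISE) responds to the activity `x` of its
primary ion with a potential (emf, mV) described by the empirical
Nikolskii–Eisenman parameterisation

    emf = a + b · log10(x + c) + ε,      ε ~ Normal(0, σ²)

* `a` (mV) — baseline potential; an electrochemical offset with no
  physical scale constraint.
* `b` (mV/decade) — response slope. Its theoretical (Nernstian) value is
  `1000·ln(10)·R·T / (z·F)` with the valence `z` of the primary ion and
  absolute temperature `T`: +59.16 mV/decade for a monovalent cation at
  25 °C, +29.18 mV/decade for a divalent cation at 21 °C. Constants are
  fixed at R = 8.31446 J mol⁻¹ K⁻¹ and F = 96485.33 C mol⁻¹ so the value
  is bit-reproducible.
* `c` (activity) — empirical interference parameter. For `x ≪ c` the
  response is flat (indistinguishable from a blank); for `x ≫ c` it is
  linear in `log10 x` with slope `b`. `c` is treated as a single
  empirical constant; no decomposition into selectivity coefficients.
* `σ` (mV) — emf noise standard deviation.

All logarithms are base 10 (`log10x` data columns, "mV/decade" slopes).

## Limit of detection

The detection limit LOD_{α,β} is the smallest activity distinguishable
from a blank with false-positive rate α and false-negative rate β
(defaults α = β = 0.05). With normal noise the decision threshold against
a blank is `y_crit = a + b·log10(c) + sign(b)·z₁₋α·σ`, and solving the
false-negative condition at the LOD gives the closed form

    LOD = c · (10^((z₁₋α + z₁₋β)·σ/|b|) − 1)

where `z_q` is the standard-normal quantile. The implementation verifies
this by construction: simulated blanks exceed the threshold with rate α
and simulated samples at the LOD fall below it with rate β (Monte-Carlo
test at n = 10⁵, tolerance ±0.01). Because the posterior of (b, c, σ) is
sampled, the posterior of log10 LOD is obtained by applying the closed
form to every draw; the reported point estimate is its median, which is
robust to the strong right skew this transform produces. The classical
intersection-of-lines LOD is deliberately not implemented.

## Priors

Weakly informative and scale-aware, identical in form for every sensor:

| Parameter | Prior | Rationale |
|---|---|---|
| a | Normal(median calibration emf, 1000²) | effectively flat over any plausible baseline |
| b | Normal(Nernst slope for (z, T), (slope/2)²) | encodes the Nernstian expectation without forcing it; sign carried by z |
| log10 c | Uniform(min log10x − 5, max log10x + 1) | c spans decades; support generously brackets the design |
| σ | Half-Normal(25 mV) | flat near 0, excludes absurd noise |
| log10 x_j | Uniform(min log10x − 3, max log10x + 1) | unknown activities restricted to the region the calibration can speak to |

Unknown activities are parameterised on the log10 scale and are therefore
strictly positive; a true blank (x = 0) is admitted in forward simulation
but not as an estimate.

## Inference

Sampling is by adaptive Metropolis-within-Gibbs: one normal random-walk
proposal per scalar unknown per sweep, on transformed coordinates
(log10 for c, log for σ, identity for a, b and log10 x). Proposal scales
adapt per chain and parameter during burn-in with a Robbins–Monro step
(gain t^−0.6) towards the 0.44 acceptance rate that is optimal for scalar
random walks, and are frozen afterwards so the retained draws come from a
genuine Markov chain. Chains are vectorised, so a sweep costs one batched
density evaluation per parameter.

One further coordinate choice matters: the intercept is sampled as
`a' = a + b·m` with `m = mean(log10(x + ĉ))` per sensor, where `ĉ` comes
from a coarse profile-OLS scan of c. Because `a` is defined several
decades outside the calibration range, (a, b, c) are nearly collinear in
raw coordinates and scalar updates barely move; centering at the
effective design mean removes most of that correlation (roughly a
four-fold gain in effective sample size in the lead-like scenario). `m`
is a fixed constant per run, so the posterior is unchanged.

Defaults: 4 chains, 5000 burn-in, 10 000 retained draws per chain,
thin 1, seed 1 — desk-scale (tens of seconds to ~2 minutes for a 3-sensor
array with 17 samples) with healthy effective sample sizes. Tests and the
acceptance script use smaller, stated configurations (2–4 chains,
1500–5000 retained draws) chosen to keep replicate studies fast while
leaving Monte-Carlo error well inside the tolerances they assert.

Initial values: per sensor, OLS of emf on log10x over the ceil(n/2)
highest-activity points (a Nernstian-region proxy) gives a and b; c
starts at the smallest calibration activity and σ at the residual SD of
that line (floored at 0.1 mV, since an exact fit gives a useless zero);
unknown activities start at the classical inverse (Basic) or classical
standard-addition estimate (Standard Addition), falling back to the
middle of the calibration range when noise makes the classical estimator
undefined. Chains beyond the first jitter these starts deterministically
from the seed so convergence diagnostics see overdispersed starts.

Diagnostics: split-chain R-hat (classic Gelman–Rubin on half-chains;
degenerate constant draws report 1 by convention) with a warning attached
to any fit where R-hat > 1.05, and bulk effective sample size via arviz.
Summaries are posterior medians with equal-tailed 50% and 95% percentile
intervals (not HPD), nested by construction.

## Quantification

Calibration and experimental data are fitted jointly in a single
posterior, so calibration-parameter uncertainty propagates into the
activity estimates rather than being fixed at characterisation values.
In Basic format each experimental reading contributes
`emf_ij ~ Normal(a_i + b_i·log10(x_j + c_i), σ_i)`; in Standard Addition
format the before/after pair contributes two such terms, the second at
the mixed activity `(x_j·V_s + conc_add·V_add)/(V_s + V_add)`. Sensors
pool automatically through the shared `x_j`, and a noisy sensor's terms
carry weight 1/σ_i², which is what down-weights poor sensors without any
explicit rule. Missing (sensor, sample) pairs are simply absent terms, so
unbalanced arrays are supported. In the all-Nernstian single-sensor limit
with c pinned near zero, the posterior activity interval reproduces the
classical inversion of an OLS prediction interval (verified against
statsmodels within 10% on a 12-point design; at very small n the
half-normal σ prior makes the Bayesian interval a few percent wider than
the t-based one, which is the expected prior effect, not a defect).

## Synthetic data

The generator draws emf values exactly from the model: curve plus
independent normal noise. The default lead-like scenario fixes the study
conditions: three divalent-cation (z = 2, 21 °C) sensors with parameters
(a, b, c, σ) = (176, 29.5, 2.18e-6, 1.42), (158, 29.0, 1.5e-6, 1.0),
(190, 28.8, 3.0e-6, 2.0); a seven-point decade-spaced calibration at
log10 x = −9 … −3 (three points in the Nernstian region given c ≈ 2e-6);
17 samples with activities log-uniform on [−6.5, −3.5]; standard
addition with V_s = 10, V_add = 1, conc_add = 1.1e-3. Sensor #1 uses the
canonical published point estimates for a lead-in-soil solid-contact ISE;
the companion sensors are plausible same-batch variants. What passing
tests on these data show is that the estimation machinery is correct and
well calibrated under the stated model; they do not probe drift,
hysteresis, liquid-junction effects, activity-coefficient corrections or
non-normal noise, none of which are simulated.

## Numerical choices and edge cases

* Support bounds: |log σ| < 23 and log10 c inside its uniform support are
  enforced in the density (−∞ outside), which keeps every exponential
  finite without clipping retained draws.
* `invert_basic` refuses emf values below the blank plateau
  (x = 10^((y−a)/b) − c < 0) rather than returning a negative activity.
  Round-trip identity holds to 1e-10 relative for x down to ~c/1000;
  below that, double-precision cancellation in x + c dominates.
* The classical standard-addition initial estimate returns "undefined"
  (None) when noise makes its denominator non-positive; the caller falls
  back to mid-calibration. Only chain starts depend on it.
* `c = 0` in the plug-in LOD returns 0 with a warning: a sensor with no
  interference floor detects arbitrarily small activities under this
  model, which is a sign the model, not the sensor, is wrong.
* File parsing converts cells with correctly-rounded `float()` so a
  write/read cycle is bit-identical; pandas' fast parser is off by one
  ulp on some inputs and is not used for the numeric columns.
* Validation is strict: sensor ids must be contiguous 1..n (no silent
  relabelling), every sensor needs ≥ 4 calibration points (four unknowns),
  duplicate (sample, sensor) measurements are rejected.

## Known limitations

* Single analyte, single ISE type per dataset; no selectivity-coefficient
  estimation; no array-level LOD (the per-sensor LOD is reported).
* Scalar Metropolis updates mix slowly when a sensor's calibration barely
  constrains the bend of the curve; the R-hat warning is the guard. The
  centering trick removes the dominant correlation but b and log10 c
  remain moderately coupled.
* Equal-tailed intervals can be conservative for the strongly skewed
  standard-addition posteriors near the detection limit; medians remain
  meaningful there.
* Input files are assumed to contain liquid-junction-corrected emf and
  activity-scale concentrations; no Henderson or Debye–Hückel corrections
  are applied.
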