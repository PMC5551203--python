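# Methods

## The model

`pondnit` simulates the nitrogen cycle of a shallow waste stabilization
pond treated as a single, completely mixed continuous stirred tank reactor
(CSTR).  Three dissolved pools are tracked, all in mg N/L: organic
nitrogen (ON), ammonia nitrogen (NH3) and nitrate nitrogen (NO3).  Each
pool obeys a hydraulic mass balance plus reaction terms:

    dON/dt  = (Qi/V)·ONin  − (Qe/V)·ON  − rm − rs + r1 + r2
    dNH3/dt = (Qi/V)·NH3in − (Qe/V)·NH3 − r1 + rm − rv − rn
    dNO3/dt = (Qi/V)·NO3in − (Qe/V)·NO3 + rn − r2 − rd

with influent/effluent flows `Qi`, `Qe` (m³/d) and pond volume `V` (m³).
The seven volumetric rates (mg/L/d):

| rate | process | law |
|------|---------|-----|
| rm | mineralization (ON → NH3) | `kmin · T · ON`, temperature-linear first order |
| rn | nitrification (NH3 → NO3) | `(µn/Yn) · NH3/(Kn+NH3) · DO/(K1+DO) · CT · CpH` |
| rs | sedimentation (permanent ON loss) | `Rs · ON` |
| rd | denitrification (NO3 loss) | `R20 · θ^(T−20) · NO3` |
| rv | ammonia volatilization | `NH3 · 0.0566 · e^{0.13(T−20)} / (d·(1+10^{10.5−0.03T−pH}))` |
| r1 | microbial NH3 uptake | `µmax20 · θ^(T−20) · NH3/(K2+NH3) · ON · p1` |
| r2 | microbial NO3 uptake | `µmax20 · θ^(T−20) · NO3/(K3+NO3) · ON · p2` |

Nitrification uses the Downing environmental factors
`Kn = 10^(0.051·T − 1.58)`, `CT = e^{0.098(T−15)}`, and
`CpH = 1` for pH ≥ 7.2, decreasing linearly below and floored at 0 (the
linear form would go negative near pH 6; inhibition cannot be negative).
Microbial biomass is not an explicit state: uptake is proportional to ON
(biomass taken proportional to organic nitrogen), and `µn/Yn` acts as a
volumetric substrate-utilization rate with implicit unit biomass.

Two formulation choices deserve note.  First, denitrification is a
nitrate **sink** (−rd); the flag `literal_eq4_sign=True` flips it to a
source for comparison with formulations that write +rd, but a source term
contradicts both the chemistry and the observed negative relationship
between `R20` and nitrate.  Second, the nitrification prefactor is the
quotient `µn/Yn` (substrate utilization = growth / yield); only the
quotient produces the expected negative dependence of nitrate on the
yield coefficient.

### Parameters

Nine constants are calibratable; defaults are the calibrated values for
the tropical pilot pond the package is built around:

| name | meaning | unit | default |
|------|---------|------|---------|
| θ (`theta`) | Arrhenius temperature base for biological rates | – | 1.01 |
| `Rs` | ON sedimentation constant | 1/d | 0.050 |
| `K1` | Nitrosomonas half-saturation for DO | mg/L | 1.26 |
| `K2` | ammonium half-saturation for uptake | mg/L | 16.20 |
| `K3` | nitrate half-saturation for uptake | mg/L | 2.0 |
| `R20` | denitrification constant at 20 °C | 1/d | 0.26 |
| `Yn` | Nitrosomonas yield | mg/mg | 0.163 |
| `µn` (`mun`) | Nitrosomonas growth rate | 1/d | 0.009 |
| `µmax20` (`mumax20`) | max microbial growth rate at 20 °C | 1/d | 0.13 |

Fixed structural constants: `kmin = 0.002 /(°C·d)` (mineralization), and
the uptake preference factors `p1 = 0.9`, `p2 = 0.1` (`p1 + p2 = 1`).
The preference split is not tabulated anywhere authoritative; microbes
consume nitrate only when ammonia is scarce, so p1 ≫ p2, and 0.9/0.1 is
the package's fixed choice (configurable).

### Numerics

The ODE system is integrated with LSODA (stiff-capable, adaptive) at
rtol 1e-6 / atol 1e-9.  Forcing (temperature, pH, DO, influent
concentrations, flow) is interpolated piecewise-linearly between records;
simulation does not extrapolate outside the forcing span.  The state is
clipped at zero inside the right-hand side, so concentrations never go
negative.  A fast scalar closure evaluates the rates inside the
integrator; a vectorized implementation of the same formulas records the
rate breakdown at output times, and a unit test pins the two paths
against each other.  Mass-balance closure (inflow − outflow − sinks =
storage change) holds to better than 0.1% of annual throughput with daily
outputs and trapezoidal re-integration.

## Synthetic scenario

The pond's field observations are not publicly deposited, so the package
generates scenarios with the study's statistical structure: a
20.5 × 1.2 × 0.80 m pond at 10 d hydraulic retention time, influent means
10.24 / 16.8 / 1.03 mg/L (ON / NH3 / NO3), weekly effluent sampling over
364 days, tropical climate (28 °C mean, ±3 °C annual sinusoid, pH
7.8 ± 0.2, DO 4 ± 1 mg/L seasonal).

Random components and why they look the way they do:

* **Influent concentrations** are lognormal with CV 0.15 and AR(1)
  persistence (correlation time 7 d).  Septic-tank effluent drifts on
  week scales; purely independent daily noise would be averaged away
  almost entirely by a 10-day-HRT reactor and leave the effluent
  implausibly smooth.  With 7-day persistence the realized annual mean
  stays within ~5% of the configured mean.
* **Water temperature** adds AR(1) noise of sd 1.5 °C (5 d correlation)
  to the annual sinusoid.  A 0.8 m open pond tracks synoptic weather —
  monsoon cloud cover and rain move daily-mean water temperature by one
  to a few °C on multi-day scales.
* **Dissolved oxygen** adds AR(1) noise of sd 0.8 mg/L (5 d correlation):
  algal photosynthesis and the same weather variability dominate DO in
  facultative ponds.  **pH** is AR(1) around its mean with sd 0.2.
* **Observations** are the truth simulation sampled weekly with
  multiplicative Gaussian noise (CV 0.05), clipped at zero — the standard
  truth-plus-noise construction for parameter-recovery testing.

All streams derive from a single scenario seed (observation noise on a
separate child stream), so a scenario is reproducible bit-for-bit.

What the generator does **not** emulate: real 2014–2015 Thai weather,
rainfall/evaporation water-balance terms, diurnal cycles (sampling is
always mid-morning in the study design), sensor drift, or correlated
observation errors.  Passing recovery tests therefore show that the
inference machinery works under the model's own assumptions with
realistic variability — not that the model is structurally adequate for
any particular real pond.

## Calibration

The objective is the unweighted mean of the three per-variable
Nash–Sutcliffe efficiencies (NSE = 1 − SSR/SST) on the calibration window
(the first half of the observation span by default, mirroring the
half-year calibration / half-year validation design).  How the three
variables are combined is not prescribed anywhere; the unweighted mean is
the package's choice, with optional weights.

Stage 1 — controlled random search ("pseudo" random search, Price
style with the CRS2 best-point refinement): a population of 5·dim points
in the bounds box; each iteration reflects a random population member
through the centroid of a simplex anchored at the current best point and
replaces the worst member on improvement.  The reflected pole may
coincide with a centroid member, which yields occasional contraction
moves that refine the neighborhood of the optimum.  Budget counts total
objective evaluations (default 500) including the initial population.

Stage 2 — adaptive Metropolis: a Gaussian error model per variable whose
variances are frozen from the residuals at the stage-1 optimum (they are
not sampled); uniform prior on the bounds box (out-of-bounds proposals
rejected); proposal covariance re-estimated from the chain history every
100 steps with the standard 2.38²/dim scaling; default 5000 samples,
burn-in 20%, no thinning.  Delayed rejection is deliberately omitted —
plain adaptive Metropolis mixes adequately on this 9-parameter posterior
and is simpler.

The reported best fit is the highest-mean-NSE point seen in either
stage.  Each chain evaluation also records the objective and the three
per-variable NSEs, which the GLUE stage reuses without re-simulation.

Bounds: ±10% around the current parameter vector for recovery and
uncertainty work, or published literature ranges (single published values
widened ±50%) for realism experiments.

## Sensitivity, identifiability, uncertainty

**Local sensitivity** uses central finite differences with relative step
1e-4 (small enough for accuracy, large enough to sit above the 1e-6
solver tolerance).  Entries are scaled dimensionless:
`S = (∂y/∂θ)·θ/σ`, with σ the observation standard deviation per variable
(mean-scaling available).  Parameters are summarized by
L1 = mean|S| and L2 = rms(S) and ranked by L1; a large L1−L2 gap flags
heavy-tailed sensitivity in time.

**Collinearity** of a parameter subset is `1/√λ_min` of the cross-product
of unit-normalized sensitivity columns; 1 means orthogonal (jointly
identifiable), values above ~15 practically unidentifiable.  All subsets
up to size 3 are enumerated by default (all 2⁹ behind a flag); a zero
column is flagged infinite rather than raised.  A structural caveat this
analysis exposes: `µn` and `Yn` enter the model only through the quotient
µn/Yn, so their columns are exactly anti-parallel and the pair's index is
unbounded — only the ratio is identifiable.  Any finite measured value
for that pair reflects finite-difference noise, not information.

**Global sensitivity** draws parameter vectors uniformly in the bounds
box, simulates each over the forcing span, records the time-mean of each
output, and reports the Pearson correlation of every parameter against
every mean output.  The time-mean response is the summary of record;
per-week responses are out of scope.  Failed simulations are dropped
(at most 10%).

**Prediction envelopes** simulate up to 500 evenly thinned post burn-in
chain samples and report per-time min / median / max per variable.

**GLUE**: each sampled parameter set is classified per output variable as
behavioral (NSE ≥ 0 — at least as good as predicting the observed mean)
or non-behavioral (NSE < 0).  The ensemble defaults to the MCMC chain
(with fresh uniform draws as an option), classification is per variable
with an additional all-variables joint flag, and the separation between
behavioral and non-behavioral parameter CDFs is quantified by the
Kolmogorov–Smirnov distance — a scalarization of the visual
"far apart CDFs = sensitive parameter" criterion.  Likelihood-weighted
prediction quantiles (classic 5–95% GLUE bands) are not produced.

## Problem sizes

The default experiment sizes are those of the study workflow: 364 days of
daily forcing, 52 weekly observations split 26/26 into calibration and
validation, 500 random-search evaluations, 5000 MCMC samples, 1000
uniform draws for global sensitivity.  The test suite exercises the same
machinery on shorter scenarios (56–182 days) plus one full-scale recovery
experiment.

## Known limitations

* DO, pH and temperature are forcing, not states; there is no
  algae–bacteria feedback, no nitrite pool, no sediment diagenesis, no
  stratification.
* The nitrification rate has implicit unit biomass; its magnitude is not
  transferable across ponds without recalibrating µn/Yn.
* The (µn, Yn) pair is structurally unidentifiable (only the ratio
  matters); joint estimates of both are prior-driven.
* The Gaussian error variances are fixed after stage 1 rather than
  sampled, so posterior widths are conditional on that error estimate.
* Multi-chain convergence diagnostics are limited to split-half checks.
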