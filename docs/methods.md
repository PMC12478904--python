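# Methods

## Model and assumptions

The package couples two contagions in one closed population: a pathogen
and worried-well behaviour (outbreak anxiety strong enough to alter
behaviour in the uninfected). Both spread by contact — the pathogen from
the infected compartment I_P only, worry from both I_P and the
worried-well compartment I_W. The model is formulated in population
fractions with S + I_P + I_W + R_P = 1 and makes these assumptions:

- **No demography or mortality.** The time scales of interest are the
  early months of an outbreak, so the population is constant.
- **Asymmetric immunity.** Recovery from the pathogen confers temporary
  immunity to *both* pathogen and worry (compartment R_P, waning at
  δ_P); recovery from worry confers none — the formerly worried return
  straight to S and can be re-worried.
- **Worry decays by "pandemic fatigue"**, modelled as exponential
  recovery at rate γ_W.
- **Behaviour enters through one dial.** A modifier α > 0 multiplies the
  pathogen force of infection acting on the worried-well only. Cautious
  behaviour (α < 1) reduces their effective contacts, protesting
  behaviour (α > 1) amplifies them, α = 1 leaves exposure unchanged.
- **Deterministic mean-field dynamics.** No stochasticity, delays, age
  structure, or time-varying parameters.

Threshold analysis is closed-form: R₀ = max(β_P/γ_P, β_W/γ_W), and the
disease-free equilibrium's Jacobian in (I_P, I_W, R_P) is lower
triangular with eigenvalues (β_P−γ_P, β_W−γ_W, −δ_P), so stability is
exactly R₀ < 1 (given δ_P > 0). R₀ is independent of β_WP: the sick are
already vectors of worry, so extra worry-from-sick transmission does not
create a new invasion route.

## Parameters, units, defaults

All rates are per day; all internal time is in days (the 50-week default
horizon is 350 days).

| parameter | meaning | default | basis |
|---|---|---|---|
| α | behavioural modifier | 1.0 | neutral default; regimes below |
| β_P | pathogen transmission | 0.74 | pathogen R₀ ≈ 10.3 with 14-day infectious period |
| β_W | worry-from-worried transmission | 0.7 | worry R₀ = 9.8, slightly below the pathogen's |
| β_WP | worry-from-sick transmission | 0.7 | set equal to β_W absent separate estimates |
| γ_P | pathogen recovery | 1/14 | two weeks symptom onset → clearance |
| γ_W | worry recovery | 1/14 | worry assumed to persist as long as illness |
| δ_P | immunity waning | 1/240 | eight-month immune period |
| I_P(0), I_W(0) | initial seeds | 0.01, 0.01 | 1% infected, 1% worried |

Note the stored default is β_P = 0.74 exactly; since 0.74 × 14 = 10.36,
the reported pathogen reproduction number is 10.36, with 10.3 understood
as the rounded figure from which β_P was derived. Equation-level code is
parameterized by β_P, not by R₀.

The behavioural regimes are named presets over α: cautious 0.5, default
1.0, protesting 1.5. The cautious/protesting values are this package's
choice — symmetric about 1 and clearly inside each regime — and every
regime-level conclusion is asserted as an ordering (largest infection
peak under protesting, earliest burden peak under protesting, largest
worry-to-infection ratio under cautious), checked both for the presets
and for randomized α draws within each regime, never as a point value.

## Diagnostics

`summarize` reports peak values/times of I_P, I_W and the burden
I_P + I_W, the first upward crossing of I_P over I_W, and the peak of
the ratio I_W/I_P. Peaks found on the output grid are refined by a local
quadratic through the three bracketing points (falling back to the grid
point at boundaries or flat brackets); the crossing is refined by linear
interpolation, with an exact-tie interval resolved to its left endpoint.
The ratio is computed only where I_P ≥ 1e−12 (missing, never ±inf,
below); since I_P stays strictly positive from any positive seed, the
floor only guards exact-zero initial data.

## Numerical choices

- Integration: adaptive explicit Runge–Kutta (SciPy RK45) — the system
  is non-stiff at these parameter scales — with rtol 1e−8, atol 1e−10,
  sampled on a uniform grid of 0.1 day. Tests verify that halving the
  grid moves peak times by < 0.1 day and that tightening tolerances
  ten-fold moves every summary number by < 1e−6 relative, and check the
  first simulated day against an independently coded fixed-step Euler
  integrator at step 1e−4 day.
- Conservation: enforced at 1e−9 at state construction, 1e−6 along
  trajectories, 1e−12 on the algebraic identity that the four
  derivatives sum to zero — separating construction round-off, solver
  error and exact algebra.
- Negative round-off: output components in [−1e−9, 0) are clipped to 0;
  anything below −1e−9 raises, distinguishing round-off from solver
  failure.

## Calibration

`generate_observations` samples I_P, I_W and/or their sum at given times
and applies independent multiplicative lognormal noise exp(N(0, σ²)),
seeded; randomness lives only there. `fit` recovers any named parameter
subset by bounded trust-region least squares (SciPy `least_squares`,
finite-difference Jacobian) on log-transformed channels floored at
1e−10 — the log scale matches the multiplicative noise model and stops
the epidemic peak from dominating the residual. Optimization is local
from a user-supplied guess; multi-start is the caller's responsibility.
Each fit reports the singular values of the residual Jacobian at the
optimum and names any parameter combinations whose singular value falls
below 1e−6 of the largest — the fingerprint of a non-identifiable
(ridge) fit — rather than returning a silent point estimate.

The synthetic generator emulates noisy prevalence curves of the two
compartments. It does **not** emulate reporting delay, under-ascertainment,
day-of-week effects, or the fact that real surveillance cannot separate
I_P from I_W without asymptomatic testing — which is precisely the
motivating problem. Passing recovery tests therefore demonstrates
self-consistency of the inference machinery under the stated noise
model, not recoverability from real surveillance data.

## Design choices on genuinely open points

- **The sensitivity sweep runs in the default regime (α = 1).** The
  initial-condition sweep varies the worried-well seed
  I_W(0) ∈ {0.001, 0.01, 0.1} with I_P(0) = 0.01 fixed, S(0) absorbing
  the difference and R_P(0) = 0.
- **Sweep interpretation:** "ten times smaller/larger" scales the
  worried-well seed only; the infected seed stays at 1%.
- α is carried inside `ModelParameters` rather than as a separate regime
  type; regimes are named presets, with overrides validated against each
  regime's inequality.

## Known limitations

- Only the disease-free equilibrium is analysed; endemic equilibria and
  their stability are out of scope — the focus is early-stage transient
  dynamics.
- At the default 1% seeds and α = 1, the peak worry-to-infection ratios
  over the sweep are 1.84 / 2.31 / 10.0. The first two are sensitive to
  both the seed size and α (smaller seeds and cautious α push them up —
  e.g. α = 0.5 gives 2.12 / 2.61 / 10.0), so ratio-based conclusions
  should be read as regime- and seeding-dependent rather than universal
  constants.
- Worry is assumed to spread like a pathogen; real psychological
  contagion (broadcast media, online networks) need not follow
  mass-action contact dynamics.
- No feedback from sustained worry onto policy or behaviour beyond the
  static α, and no dynamic availability of asymptomatic testing.
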