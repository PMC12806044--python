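# Methods

## Model

The package simulates batch fermentation of a lactic acid bacterium on a
single limiting sugar as four coupled ODEs in the canonical order
(S, Q, X, A): substrate, physiological state, biomass, product. Growth is
Monod in substrate and non-competitively inhibited by the product through a
Hill factor with exponent n_A; product formation follows Luedeking–Piret
kinetics (a growth-associated term α·dX/dt and a maintenance term β·X);
substrate consumption is the yield-weighted sum of both sinks. The
distinctive element is the second, regulatory pathway: the physiological
state Q — proportional to the intracellular level of a critical
substrate-processing enzyme — multiplies growth through the adjustment
factor μ_Q = Q/(1+Q) and accumulates at rate ν·f_Q(S)·Q, where
f_Q(S) = 1/(1+(S/K_Q)^n_Q) encodes suppression of enzyme synthesis by high
substrate. Lag phase is therefore a state variable, set jointly by the
inoculum's preculture history (Q₀) and the medium (S₀), rather than a fitted
delay.

Assumptions: a well-mixed batch (no feed, no dilution), no death phase, no
pH/temperature dependence, concentrations in g/dm³ and time in hours with no
unit inference. Two structural ties follow the classical lag-phase
literature and are kept during fitting unless explicitly untied: ν = μ_max
("bottleneck" adaptation) and K_Q = K_S. The Hill exponents are fixed at
n_Q = 2 and n_A = 5 and accepted as positive reals.

Limiting cases (enforced by tests): K_Q → ∞ and K_I → ∞ collapse the system
to the Baranyi–Roberts lag model; additionally Q → ∞ gives pure Monod
growth.

## Parameters

| symbol | meaning | units | default / bounds |
|---|---|---|---|
| μ_max | maximum specific growth rate | 1/h | fit bound [0.01, 5] |
| ν | adaptation rate | 1/h | tied to μ_max |
| K_S | Monod constant | g/dm³ | fit bound [0.1, 200] |
| K_Q | substrate-inhibition constant of enzyme synthesis | g/dm³ | tied to K_S |
| K_I | product-inhibition constant | g/dm³ | fit bound [0.1, 200] |
| n_Q, n_A | Hill exponents | – | fixed 2 and 5 |
| α | growth-associated product coefficient | g A / g X | fit bound [0, 20] |
| β | maintenance product coefficient | g A/(g X·h) | fit bound [0, 5] |
| γ_X/S, γ_A/S | pathway yields | g/g | fit bounds [0.01, 5] |
| Q₀ | inoculum physiological state | – | fit bound [0.01, 10] |

The fit bounds are physically plausible ranges for LAB batch culture, wide
enough not to bind at realistic optima.

## Numerics

**Integration.** The reference integrator is forward Euler on a uniform
grid, compiled with numba; the default step dt = 0.01 h is far below the
fastest characteristic time (1/μ_max ≥ 0.2 h at the bound). Substrate
exhaustion is handled by step shortening: if an update would drive S
negative, the step is scaled so S lands exactly on zero, with the biomass
and product updates scaled by the same fraction (rates evaluated pre-step);
thereafter only Q evolves (f_Q(0) = 1). Because dS/dt is evaluated in the
substituted form −(1/γ_X/S + α/γ_A/S)·dX/dt − (β/γ_A/S)·X, the balance
identity S₀ − S = (X−X₀)/γ_X/S + (A−A₀)/γ_A/S holds to float roundoff at
every grid point, clamping included — the tests require < 1e-9·S₀ and
observe ~1e-14. An adaptive LSODA integration (rtol 1e-9, exhaustion as a
terminal event, analytic Q-growth afterwards) serves as an independent
cross-check; Euler at dt = 0.01 h agrees within 1% in X(t) and halving dt
halves the deviation (first order), which is the convergence self-check.

**Stationarity.** Scans integrate each condition until the biomass rate
falls below 1e-6 g/(dm³·h) *after* its peak (the past-peak guard prevents a
stop during lag), capped at 200 h.

**Trait extraction.** Trajectories are dense and smooth, so derivative-based
traits use centred finite differences smoothed over a 5-point window purely
to suppress float noise. The specific growth rate is the maximum of
d(ln X)/dt ("slope of the log phase" without a user-marked interval). Two
lag conventions are implemented: the default *derivative-peak* (time of
maximum dX/dt) and the classical *tangent* construction (back-extrapolation
of the steepest ln X tangent to the inoculum level). Under the shipped
presets the derivative-peak lag is strictly increasing in S₀ for all tested
Q₀; the tangent lag is not, because the tangent construction divides the
adaptation deficit by the measured μ, itself S₀-dependent. Yield is
evaluated at the first time S < 1% of S₀ (or at the end of the run), i.e. at
effective exhaustion. Productivity is (A(t)−A₀)/t on the grid excluding
t = 0. The Pirt decomposition regresses 1/Y on 1/μ by OLS separately below
and above S꜀, and additionally reports consecutive pairwise slopes above S꜀
to expose the substrate dependence of the maintenance coefficient. S꜀ itself
is the argmax of μ(S₀) on the scan grid, refined by a 3-point parabola
(stable to < 0.1 g/dm³ under grid refinement).

**Estimation.** The objective is the plain unweighted sum of squared
differences in S, X and A between simulation and observation over all
datasets, with each dataset simulated from its own (S₀, X₀, A₀) and a single
shared Q₀ (one inoculum). Observation times are linearly interpolated on the
dense grid. Minimisation is bounded trust-region-reflective nonlinear least
squares on the stacked residual vector, terminating when the relative
parameter step falls below 1e-4, with a seeded Latin-hypercube multi-start
(default 16) because the objective has local minima in the production block.
Standard errors are Gauss–Newton (σ²(JᵀJ)⁻¹ at the optimum). A draw that
fails to integrate contributes large penalty residuals so the optimiser can
continue. An optional weighted mode scales each observable's residuals by
its across-dataset RMS; it is off by default so that the scalar objective is
exactly the plain sum of squares defined above.

## Synthetic data

The generator emulates the shape of published LAB batch datasets: sparse
sampling (default 13 points over 0–24 h, denser early), three observables
(S, X, A), positive concentrations, and multiplicative log-normal noise with
cv = 0.05 by default (mean-1 multiplier, so replicate CV converges to the
nominal value; an additive-Gaussian mode is provided). Tables record their
generating truth in metadata. What it does **not** emulate: instrument
error structure (OD-to-dry-weight conversion, HPLC calibration drift),
autocorrelated within-run errors, replicate culture variability, or missing
early-lag observations — so passing recovery tests show identifiability
under idealised iid noise, not robustness to real measurement pathologies.

Strain presets pin every published anchor value of the three study systems
(K_S = 8 g/dm³, Q₀ = 0.6, X₀ = 0.02 g/dm³ and conditions 26/43 g/dm³ for
*L. bulgaricus*; Q₀ = 0.60 and conditions 35.5/48.1 g/dm³ for *L. casei*;
β = 0 and conditions 11/22 g/dm³ for *L. plantarum*). The remaining
constants are synthetic placeholder truths — the original per-strain fitted
tables are not redistributable — calibrated once against each system's
published regime (bulgaricus: bell-shaped μ(S₀) with S꜀ near 14.3 g/dm³ and
lag monotone in S₀ at all four Q₀ values; casei: monotone μ(S₀) at Q₀ = 0.6,
a peak near 17.1 g/dm³ at Q₀ = 0.2, peak productivity ≈ 2.4 g/(dm³·h)
within 5–10 h at S₀ = 35.5 g/dm³; plantarum: growth-associated production
with the inoculum-size phenomenology) and then frozen. All three truths sit
in the low-biomass-yield regime (Y ≈ 0.03–0.04 g/g) characteristic of
homolactic fermentation, where most carbon leaves as lactate; within the
anchored regime the bulgaricus S꜀ is pinned by (K_Q, n_Q, Q₀) at ≈ 14.6
g/dm³, within 0.4 g/dm³ of the published 14.3 g/dm³.

## Design choices

- **Noisy recovery study (two-stage).** At 5% multiplicative noise on two
  conditions × 12 time points, the production block (K_I, α, β, γ_A/S) is
  collinear: α·dX/dt and β·X are nearly proportional over a sigmoid run, and
  the substrate balance constrains only the combination
  1/γ_X/S + α/γ_A/S, so the joint fit can trade γ_X/S against the others
  across orders of magnitude. The recovery study therefore first fits all
  eight quantities to noiseless data, then re-estimates the growth block
  (μ_max, K_S, γ_X/S, Q₀) from each noisy realisation with the production
  block pinned at the stage-1 values — the question it answers is "are the
  growth parameters recoverable from noisy data once the stoichiometry is
  known", which is the identifiable version of the question. The noiseless
  all-parameter fit is exact to numerical precision, so stage-1 pinning
  introduces no bias.
- **Lag convention.** The derivative-peak reading is the package default
  (it is the operational definition used with this model family); the
  tangent method is provided because it is the classical microbiological
  construction and is the one with a closed form in the Baranyi limit
  (λ = ln(1+1/Q₀)/μ_max, verified to < 5%).
- **Trade-off orientation.** Below S꜀ the model shows a genuine trade-off:
  μ rises with S₀ while adaptation 1/λ falls. Above S꜀ both are suppressed
  together. Tests assert exactly this orientation.
- **Q₀ sharing.** Datasets fitted jointly share one Q₀ (same inoculum);
  per-dataset Q₀ can be emulated by fitting datasets separately.
- **Scan defaults.** S₀ grid 0.5–80 g/dm³ × 160 points (union of the
  published plotted ranges); scans are embarrassingly parallel and
  order-independent (each grid point is an independent simulation).

## Problem sizes used in the shipped studies

Scans use 160-point grids (headline S꜀ numbers) or 17–35-point grids
(qualitative monotonicity checks); recovery studies use two conditions × 12
sampling points × 3 observables, 8 multi-start fits noiseless and 10 noisy
seeds × 6 starts. These sizes were chosen so the full test suite and the
acceptance script each complete in well under a minute of compute apart from
JIT warm-up, while leaving the reported quantities stable to well within
their stated tolerances.

## Known limitations

- Forward Euler is first-order; the defaults are validated against LSODA but
  users supplying much stiffer parameter sets (e.g. μ_max near the 5 1/h
  bound with large Q₀) should reduce dt or use `simulate_adaptive`.
- The model has no death phase: post-exhaustion biomass is frozen, so traits
  extracted from data with lysis or maintenance decay will not match.
- The unweighted objective is dominated by the largest-scale observable
  (usually S); the weighted mode mitigates but does not remove the
  production-block collinearity discussed above.
- S꜀ from the derivative-peak μ is a convention-dependent quantity: trait
  extraction (smoothing window, stationarity cutoff) can move it by a few
  tenths of g/dm³.
- The physiological state Q is not observable; its scale is set by the
  μ_Q = Q/(1+Q) convention, and only Q₀ (not Q(t)) is identifiable from
  concentration data.
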