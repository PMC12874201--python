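# Methods

## Binding model and its assumptions

The package treats polyelectrolyte complexation at a sensor surface as a
bimolecular 1:1 association, P + Pa ⇌ P–Pa, with chain-level rate constants
k_on (per μM per s) and k_off (per s). Under continuous flow the analyte's
chain concentration [P]₀ is constant (pseudo-first-order condition), and the
rate law integrates to a single-exponential approach to equilibrium,

    R(t) = R_eq (1 − e^(−k_obs t)),   k_obs = k_on[P]₀ + k_off,
    R_eq = R_max [P]₀ / ([P]₀ + K_D).

Assumptions inherited from this model: one class of binding site, no
cooperativity or rebinding, reaction-limited transport (see the
transport-limited variant below), and an instrument response linearly
proportional to bound mass (taken as 0.1 pg per RU; no refractive-index
modelling). k_obs is affine in concentration *including* the k_off
intercept — the zero-concentration limit of the observed rate is the
dissociation rate, which is also how the intercept of the rate line is
interpreted.

The calibration-free molecular-weight determination rests on one additional
physical assumption: the intrinsic chain association rate k_on is the same
for both orientations of the pair (A flowed over immobilized B, or B over
A), because the elementary step — encounter of oppositely charged repeat
units — does not depend on which chain is tethered. Under that symmetry the
slope α of k_obs versus the unknown polymer's monomeric concentration obeys
α = k_on/DP, so DP = k_on/α and M_n = DP·M_o. The assumption is plausible
for electrostatically driven complexation at fixed ionic strength,
temperature and flow; it is *not* guaranteed when surface immobilization
changes chain accessibility, and the method should be treated as
orientation-symmetric only to the extent that control experiments support
it. Extrapolation to extreme molecular weights is not advised.

## Preprocessing

Raw dual-channel sensorgrams are reduced to fit-ready transients by three
affine steps, in order: (1) pointwise subtraction of the reference channel,
which carries the bulk refractive-index pulse of the analyte solution but no
binding; (2) baseline zeroing on a pre-injection window, by default the 10 s
immediately before injection (the shortest stable pre-injection stretch —
long enough to average noise, short enough to avoid drift); (3) windowing of
the association phase with time rebased to 0 at injection start. Because all
three are affine, reference subtraction and baseline zeroing commute. No
smoothing is applied by default; an optional odd-kernel median filter is
available for spiky data. Whether fits use reference-corrected or raw active
data is a flag (`use_reference`), defaulting to corrected-when-available.

## Transient fitting

One-phase (C, k_obs) and two-phase (A_fast, k_fast, A_slow, k_slow)
exponential association models are fitted by trust-region nonlinear least
squares (`scipy.optimize.least_squares`), exposed as scikit-learn
estimators. Numerical choices:

- Initialization: C₀ = max response; k₀ = 1/t₆₃ with t₆₃ the first time the
  response crosses 63.2% of C₀ (the standard single-exponential heuristic);
  the two-phase fit starts its rates at 3k₀ and 0.3k₀ with the amplitude
  split evenly.
- Bounds: k ∈ [10⁻⁶, 10] s⁻¹ (covers sub-hour to sub-second equilibration
  at 1 Hz sampling), amplitudes non-negative.
- Convergence: tolerance 1e−10 on the cost, step and gradient; up to 1000
  (one-phase) / 2000 (two-phase) function evaluations. Non-convergence
  raises a typed error carrying solver diagnostics; the two-phase wrapper
  falls back to the one-phase model, flagged `fallback`.
- Offset fixed at 0 by default (preprocessing zeroes the baseline and the
  model passes through the origin); a free-offset flag exists.
- Degenerate data (constant response) raise an error rather than return a
  boundary solution. A two-phase fit whose rates collapse (k_fast ≤
  1.05·k_slow) or whose smaller amplitude is below 0.1% of the total is
  flagged `degenerate` — the data do not support a second phase.
- Standard errors come from the Jacobian at the solution
  (σ̂²·(JᵀJ)⁻¹ with σ̂² = SS_res/(n−p)); R² is 1 − SS_res/SS_tot about the
  mean.

Model comparison reports ΔR², the small-sample-corrected Akaike criterion
difference (least-squares form, penalizing the two extra parameters), and a
Wald–Wolfowitz runs statistic on residual signs as a lack-of-fit
diagnostic. Replicates are fitted individually and aggregated as
mean ± SEM (sample SD/√n); SEM is flagged undefined for n = 1.

## Rate-line regression

k_obs versus concentration is fitted by closed-form least squares (centered
normal equations), unweighted by default: the reference dataset's published
slope/intercept are reproduced exactly by unweighted OLS on the replicate
means, so that is the default procedure; inverse-variance weighting by
replicate SEM is an option. Standard errors use the classical OLS
covariance with n−2 degrees of freedom. A negative intercept is clamped to
k_off = 0 with a warning (a rate cannot be negative); the raw intercept
stays on the rate line. Each line records its concentration basis
(polymeric μM or monomeric mM) and conversions between bases are explicit —
extracting k_on/k_off from a monomeric-basis line is a typed error.

## Molecular-weight solver and uncertainty

DP = k_on/α with both slopes on the per-μM basis; M_n = DP·M_o identically.
Reported values follow the field's rounding convention: DP to the nearest
integer, reported M_n = round(DP)·M_o to the nearest 100 g/mol (exact
values are kept alongside). Uncertainty is propagated to first order
assuming k_on and α are independent (they come from separate experiments):
se_DP/DP = √((se_kon/k_on)² + (se_α/α)²), se_Mn = M_o·se_DP. Against a
10⁵-draw Monte-Carlo oracle at the reference dataset's uncertainties the
delta method agrees to ~2%; correlation between the slopes is out of scope.

Two documented inconsistencies in the reference dataset are handled
explicitly rather than silently absorbed: (1) PEI's chain mass is quoted
both as ≈10,000 and ≈25,000 g/mol in different places; the package defaults
to 25,000, the only value consistent with the dataset's own
monomeric→polymeric conversions, and the value is configurable. (2) The
printed chain concentrations imply DP ≈ 581.4 while M_n = 25,000 with
M_o = 43.07 gives DP ≈ 580.4 (a ~0.16% mismatch); both conventions are
available — the printed concentrations are bundled verbatim, and the
pipeline accepts a chain-basis table directly (`known_basis="polymeric_uM"`)
or converts from monomeric units itself.

## Simulator: what it emulates and what it does not

The generator emulates the flow-injection protocol of the reference study:
30 s baseline hold, 300 s association, 300 s dissociation, 1 Hz sampling,
the five-step monomeric gradient (1, 0.5, 0.25, 0.125, 0.0625 mM) in
duplicate, with truth kinetics k_on = 0.03705 μM⁻¹s⁻¹ and
k_off = 0.0143 s⁻¹ by default. The active channel is baseline + a square
bulk-shift pulse spanning the injection + the closed-form binding curve +
i.i.d. Gaussian noise; the reference channel carries the same baseline and
pulse with independent noise. The square pulse is exactly what a reference
channel is designed to cancel, which the tests exploit.

Deliberate idealizations — and therefore what passing tests do *not* show
about real data: noise is white Gaussian (real instruments drift and spike;
the published instrument resolution is not mappable to an RU noise floor
without calibration, so σ = 2 RU on R_max = 1000 RU is a labelled
placeholder); the bulk shift is an ideal synchronized square pulse; there is
no baseline drift, temperature artifact or regeneration carry-over; and the
amplitude scale is arbitrary since R_max values for the reference system are
unpublished — only rate-level quantities are meaningful end to end.

All randomness derives from one integer seed via `SeedSequence` spawning:
identical configs are bit-identical, gradient traces are mutually
independent, and every output records its seed.

The transport-limited variant integrates the standard two-compartment
quasi-steady-state approximation, dR/dt = k_on·C_s·(R_max−R) − k_off·R with
C_s = (k_m·C_bulk + k_off·R)/(k_m + k_on·(R_max−R)), by LSODA at
rtol = atol = 1e−9. It converges to the closed form as k_m → ∞ (verified to
<0.1% of R_eq) and is used only for robustness checks — the reference
analysis is reaction-limited by experimental design, and no transport
parameters are fitted.

## Problem sizes

The default test and acceptance runs use 301-point transients (300 s at
1 Hz), 5-concentration gradients, duplicate injections, 50-seed replication
for stochastic checks, 1000 random designs for the least-squares oracle
comparison, and 10⁵ Monte-Carlo draws for the uncertainty oracle. These
sizes match the emulated protocol while keeping the whole suite fast; the
estimators themselves are size-agnostic.

## Known limitations

- k_off from the rate-line intercept is statistically weak when the
  gradient spans concentrations well above K_D; the dissociation phase is
  simulated but deliberately not fitted (the chosen analysis derives k_off
  from the intercept).
- The two-phase model's extra parameters are poorly constrained at low
  signal-to-noise; the degenerate/fallback flags must be honoured
  downstream.
- Published ± values on k_on/k_off in the reference dataset come from the
  original authors' fitting software and are only approximately reproduced
  by the classical OLS standard errors reported here.
- Polydispersity (M_w/M_n) is out of scope: the method yields a
  number-average quantity only.
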