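# Methods

## Scope and model

The package analyses the equilibrium solubility of sparingly soluble
monoprotic weak acids (the phenolic-acid family is the motivating case) in
water and in 1:1 sodium-salt media at 37 °C. The chain of models is:

**Quantification.** Beer–Lambert, `A = l·ε·c (+ b)`, at one analytical
wavelength per acid. The intercept `b` is fitted freely by default —
real calibrations drift — with a strict through-origin mode available.
The limit of detection is `f·σ_resid/slope` with `f = 3.3` by default
(ICH-style); both `f` and the mode are configurable because neither is a
physical constant. Replicates are aggregated *after* quantification
(means ± sample sd, n−1 denominator), matching how such data are reported.

**Total solubility vs salt molality.** The empirical smoothing form

    log10 S_T(m) = log10 S_T0 + [a_inf + (a_0 − a_inf)/(1+m)]·m

has limiting slopes `a_0` at m→0 and `a_inf` at m→∞ and degenerates to a
line when `a_0 = a_inf`. In the basis `(1, m, m/(1+m))` it is linear in
its parameters, so the fit is exact weighted linear least squares — no
iterative optimizer, no starting values, deterministic and
order-invariant. Model selection (`auto`) uses the extra-sum-of-squares
F-test at α = 0.05, preferring the line when both fits are numerically
exact.

**Ionization (SIT).** The stoichiometric ionization constant obeys

    pK(I) = pK0 − 2·D(I) + (b+ + b− − k)·I,   D(I) = A√I/(1 + B√I)

with `A = 0.4565`, `B = 1.11 kg^1/2·mol^−1/2` at 37 °C, `b+` the
H⁺/medium-anion SIT coefficient (defaults 0.12 for Cl⁻, 0.14 for ClO₄⁻),
`b−` the A⁻/Na⁺ coefficient (default 0.06, the hydrogen-salicylate
analogy), and `k` the Setschenow coefficient of the neutral acid. All
defaults are configuration-overridable; no temperature model is built in
(37 °C enters only through these constants).

**Speciation.** In a saturated solution with no added acid/base the
dissolution is the only proton source, so `[H⁺] = [A⁻]` and `[H⁺]` is the
positive root of `h² + K·h − K·S_T = 0`, evaluated in the
cancellation-safe form `h = 2KS_T/(K + √(K² + 4KS_T))`. Water
autoprotolysis is neglected: saturated solutions of these acids sit at
h ≳ 10⁻⁴ mol·kg⁻¹; a warning fires if h < 10⁻⁶. A measured pH can be
supplied to override the computed `h`. Ionic strength is identified with
the background-salt molality (ionic-medium approximation; the
≲ 10⁻³ mol·kg⁻¹ contribution of the acid's own ions is neglected
consistently in both the simulator and the analysis).

**Activity coefficients.** `log10 γ = log10(S⁰_w/S⁰)` with γ = 1 in pure
water by construction. Two origin-constrained salting models:

    constant   log10 γ = k·m
    extended   log10 γ = [k_inf + (k_0 − k_inf)/(1+m)]·m

The extended form mirrors the smoothing solubility model; it satisfies
log γ(0) = 0 exactly, reduces to the constant model at `k_0 = k_inf`, and
its local coefficient `k(m) = k_inf + (k_0 − k_inf)/(1+m)` plateaus above
m ≈ 2. A historical variant that adds a constant `k_inf` offset (and so
violates the reference state) is kept behind `printed_form=True` /
`--printed-eq12` purely for forensic comparison; it is never fitted.

**Coupling.** `k` appears inside pK(I) but is estimated from the
corrected solubilities, so `correct_total_solubility` iterates: extract
pK0 from the measured pK at the highest tabulated ionic strength
(typically 0.51 mol·kg⁻¹), compute K(I) with the current effective k(m),
correct S_T → S⁰, refit the salting model, repeat. The loop stops when
successive (k_0, k_inf) change by < 1e-10 kg·mol⁻¹ (cap 50 iterations;
each step is a handful of closed-form operations, so the tight tolerance
is essentially free and keeps the fixed point converged far below the
package's 1e-6 round-trip verification level). Convergence is fast (≈ 8
iterations in practice) because k perturbs K(I) only at second order.

## Statistical choices

- **Observation weighting.** By default every replicate enters the fit as
  one observation on the log10 scale (uniform weights, honest degrees of
  freedom). Per-point 1/sd² weighting from triplicate sds is available
  (`weighting="point_sd"`) but not default: with n = 3 the reciprocal
  sample variance has no finite mean, and such weights destroy
  confidence-interval calibration.
- **Reference-state handling.** Inside the pipeline the salting model is
  fitted jointly with the pure-water neutral solubility as a free
  intercept in log-S⁰ space (`fit_setschenow_solubility`). This is
  algebraically the origin-constrained γ fit when S⁰_w is known exactly,
  but it propagates the water point's replicate scatter into the
  parameter covariance instead of conditioning on it, which is what makes
  the reported CIs cover at their nominal rate. The strictly
  origin-constrained fit on precomputed log γ points remains available as
  `fit_setschenow`.
- **Comparisons.** One-way ANOVA (scipy `f_oneway`) with Tukey's HSD
  (scipy `tukey_hsd`), significance at adjusted p < 0.05. The degenerate
  all-groups-identical case short-circuits to "nothing significant".

## Synthetic data

`simulate_experiment` forward-simulates from a `GroundTruth`: the
*neutral-species* curve follows the smoothing form with parameters
(a_0, a_inf) — hence exact implied Setschenow truth k_0 = −a_0,
k_inf = −a_inf — ionization is added back through the SIT relation and
speciation (`S_T = s0 + √(K·s0)`), absorbances are `slope·S_T/dilution`
with multiplicative Gaussian noise and 0.001 quantization, and
calibration standards span the subclass's standard range. "Measured" pK
values at I ∈ {0.16, 0.51} mol·kg⁻¹ are emitted from the same model for
the SIT stage to consume. `log_S_T0` in the truth is the *total* water
solubility; the neutral water solubility is derived through the same
speciation, so a noise-free simulation inverts exactly.

Defaults are the study conditions: molality grid {0.16, 0.5, 1.0, 2.0,
3.0}, triplicates, 2% relative absorbance noise (the instrument
resolution is stated; the replicate error structure is not, and 2%
multiplicative is the standard spectrophotometric assumption). The
quantization step can be disabled (`quantize=False`) for exact-recovery
studies, since ±0.0005 rounding alone caps recovery at ~10⁻³.

`make_paper_like_truth` samples ground truths by rejection so the forward
curves obey the study's qualitative structure: hydroxybenzoic acids about
a decade more soluble than hydroxycinnamic ones (log10 S_T0 in
[−1.45, −0.95] vs [−2.45, −1.95]), positive Setschenow coefficients with
k_0 ≥ k_inf, pK0 in [4.0, 4.6] (typical carboxyl pK of these acids), and
a total-solubility loss at m = 3 inside the subclass's characteristic
window — 42–68% for hydroxycinnamic acids (their hallmark 40–70% salting
out), 18–55% for hydroxybenzoic. Effective calibration slopes and
dilutions (40 kg·mol⁻¹ / 5× benzoic, 100 kg·mol⁻¹ / 1× cinnamic) put
cuvette readings inside the standard ranges at absorbances 0.1–1.

What the simulator does **not** emulate: full band shapes (one analytical
wavelength only), baseline drift, kinetics of approach to saturation,
temperature fluctuations, correlated inter-day errors, or media beyond
single 1:1 sodium salts. Passing tests therefore demonstrate correctness
of the inference chain under idealized measurement error, not robustness
to every laboratory pathology.

## Validation design

- **Zero-noise round trip** (`validation.zero_noise_roundtrip`): simulate
  with no noise/quantization, run the whole pipeline, require every truth
  parameter (log S_T0, a_0, a_inf, k_0, k_inf, pK0) back to 1e-6
  relative; observed errors are ~1e-11, limited by the fixed-point
  tolerance.
- **Coverage study** (`validation.coverage_study`): 200 simulated
  experiments per scenario at the default noise, non-ionizing solutes (so
  the smoothing fit targets a_0/a_inf exactly; the ionization stage is
  validated separately by the round trip and the speciation oracle),
  through-origin calibration (the simulated standards have no blank
  offset, and the slope error then acts as a common factor absorbed by
  the fitted intercepts). Checks: 95% t-intervals cover the truth at
  95 ± 5 points; estimator |bias| < 2× its Monte-Carlo standard error.
- **Oracles**: the closed-form [H⁺] is compared with plain bisection on
  the charge-balance residual over a 20×20 log-grid (agreement ~1e-16
  relative); the least-squares fits are compared with brute-force
  refined grid searches, with agreement asserted in the SSE surface's own
  quadratic metric because the (log S_T0, a_0, a_inf) valley is strongly
  anisotropic — along the flat valley a lattice argmin may sit several
  nodes from the optimum at indistinguishable SSE.

## Numerical notes and degenerate inputs

- Fits reject non-positive solubilities (log scale), fewer points than
  parameters, and singular designs with specific exceptions.
- A flat or tied spectrum peak resolves to the lowest wavelength in the
  window.
- Quantified concentrations below the blank are returned as negative
  values flagged `below_blank` (raising would bias replicate means near
  zero); below-LOD and out-of-calibration-range results carry flags, not
  errors.
- `salting_out_percent` is bounded above by 100 and unbounded below
  (salting-in).
- K = 0 (non-ionizing) is handled as the exact limit h = 0, S⁰ = S_T.

## Known limitations

- Monoprotic treatment only; no polyprotic speciation or metal
  complexation.
- No mechanistic (Pitzer/UNIQUAC) activity models and no mixed
  electrolytes; the smoothing and Setschenow forms are empirical.
- Molar→molal conversion requires user-supplied densities; the package
  ships no electrolyte density correlations, so molar ionic-strength
  labels without densities are treated as metadata.
- The SIT extrapolation anchors on a single measured pK (highest
  tabulated I); the spread of pK0 over all tabulated entries is reported
  as a diagnostic (`pK0_spread`), not reconciled.
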