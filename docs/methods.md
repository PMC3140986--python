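# Methods

## Model

Fitness λ is the Malthusian growth rate in units of a lac-deleted reference
strain (λ₀ = 1 by convention). Expressing and running the lac pathway costs

    cost(δ, T, λ) = c_δ·δ + c_T·T + c_C·T/λ²,

where δ is the lac protein production rate, T = (δ/λ)·τ̂(E) the total inducer
transport rate (permease copy number δ/λ set by production balanced against
dilution by division, times the per-pump rate τ̂), and T/λ² the steady-state
concentration of the toxic co-transported species (influx divided by the
dilution rate λ and a cell volume taken proportional to λ; the volume
proportionality constant and the LacY:LacZ stoichiometry are absorbed into
c_T and c_C). Production depends on genotype and environment as

    δ = δ_max · η(λ) · (χ₀ + (1−χ₀)·h(E)),
    h(E) = Eⁿ/(Eⁿ + K_hⁿ),
    τ̂(E) = pump_factor · [E/(E+K_T)] / [E_norm/(E_norm+K_T)],
    η(λ) = (λ/λ₁)² · max(0, 1 − θ(λ/λ₁ − 1)).

η combines dilution of production into concentration (one factor λ), the
volume law (another factor λ) and a linearly decreasing constitutive
concentration with growth rate (slope θ), normalized to 1 at λ₁, the fitness
of a strain growing at one doubling per hour. Fitness is the self-consistent
fixed point of G(λ) = λ₀ − cost(δ(λ), T(λ), λ).

### Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| λ₀ | reference-strain fitness | 1 | reference units |
| c_δ, c_T, c_C | cost amplitudes | 0.06, 0.01, 0.04 | per unit phenotype |
| K_h, n_h | induction half-saturation, Hill coefficient | 0.1 mM, 2 | — |
| K_T | per-pump transport half-saturation | 0.3 mM | — |
| E_norm | concentration where τ̂ = 1 | 1 mM | — |
| λ₁ | fitness at 1 doubling/hour | 1 | reference units |
| θ | concentration–growth slope in η | 0 | dimensionless |

K_h, n_h, K_T, E_norm, λ₁ and θ are package defaults chosen to be plausible
for IPTG induction of the lac operon, not measured values. The default cost
coefficients give a constitutive wild-type-level strain a ~6% production cost
uninduced and a ~10% total cost fully induced, with the toxicity and
production terms dominating over the direct transport term — the qualitative
magnitudes competition assays report for this system. E_norm = 1 mM makes the
per-pump rate 1 at the saturating assay concentration, so δ_max is defined at
the condition used to estimate it.

### Landscape structure

In phenotype coordinates (δ, T) the fixed-point condition is the cubic
λ³ − aλ² + b = 0 with a = λ₀ − c_δδ − c_T·T and b = c_C·T, solved in closed
form (trigonometric method plus a Newton polish, which keeps branch ordering
stable near the tangency). For a, b > 0 there are exactly two positive roots
(larger stable, smaller unstable), a double root at the tangency
b = 4a³/27 (λ = 2a/3), or none. The locus where the fold closes is the
expression barrier, found per δ by bracketing the tangency condition in T.

In genotype–environment coordinates the phenotypes depend on λ, so fixed
points of G are located by a dense sign-change scan of λ − G(λ) on
(10⁻⁶λ₀, λ₀] followed by Brent refinement; roots closer than 10⁻⁶λ₀ are
merged and labeled marginal. Stability follows the crossing criterion:
stable iff G′(λ*) < 1 (central finite difference). The fitness cliff along an
axis (E or δ_max) is located by bisection on existence of a solution to
relative tolerance 1e-8. Costs diverge as λ → 0, so no fixed points survive
below the 10⁻⁶λ₀ floor; that region is handled by the dynamics as extinction.

When θ = 0 the fixed-point condition is polynomial in λ (a quartic with η
off, a cubic with η on). The inference inner loop exploits this with an
algebraic solve (`stable_lambda_fast`, companion-matrix roots plus Newton
polish on the un-multiplied residual), which the test suite checks against
the bracketing solver to 1e-9; with θ ≠ 0 it falls back to bracketing.

### Dynamics

The relaxation of the growth rate is modeled as the damped iteration
λ_{t+1} = λ_t + f·(G(λ_t) − λ_t) with time step f ≤ 1 in units of the
relaxation time, and as the matching ODE dλ/dt = (G(λ) − λ)/τ_relax
(τ_relax defaults to one reference generation). Both share the landscape's
fixed points and stability exactly; extinction is declared when λ falls to
the 10⁻⁶λ₀ floor, below which the cost terms are undefined and no steady
growth exists. The ODE is integrated adaptively (RK45, atol 1e-12) with a
terminal event at the floor.

## Estimators

At steady state the measured protein concentration is C = δ/(λV) ∝ δ/λ², so
d ≡ C·λ²/η(λ) = δ_max·(χ₀ + (1−χ₀)h(E)). With d₀ from the uninduced
condition (h = 0) and d₁ from a saturating one this inverts exactly:

    δ_max = d₀ + (d₁ − d₀)/h(E_sat),        χ₀ = d₀/δ_max.

The common approximation δ_max = d₁ (full induction, h → 1) is available as
a toggle; the exact inversion differs from it by ~1% at 1 mM with the default
induction constants and makes the estimator an exact inverse of the
generative model, which the tests exploit. Both estimators are independent
of the cost model. Standard errors come from first-order (delta-method)
propagation assuming independent errors on concentration and fitness,
validated against Monte-Carlo resampling in the tests.

Concentration units: the synthetic data report C = δ/λ² directly, i.e. units
in which a fully induced strain with δ_max = 1 at one doubling per hour has
C = 1. This is the fully-induced-wild-type normalization up to a constant
absorbed in the cost coefficients.

## Likelihood and fitting

The cost coefficients are fit by maximizing a Gaussian log-likelihood of the
observed mean fitness per strain × condition given the stable-branch
prediction λ̂(δ̂_max, χ̂₀, E). Two refinements make the score well
calibrated:

- **Replicate-variance pooling.** Standard errors estimated from 3–12
  replicates are themselves noisy and mis-calibrate a plug-in Gaussian
  score. Fitness noise is pooled across all strain × condition groups
  (homoscedastic); concentration noise is modeled as SD = a + b·|mean| with
  (a, b) fit across groups, matching the absolute-floor-plus-relative error
  structure of enzymatic assays. A toggle restores raw per-condition SEs.
- **Residual-level error propagation.** Per strain, the residuals of all
  conditions share the phenotype-estimate error, and the observed fitness of
  a base condition also enters the estimator. The score therefore uses a
  per-strain block-Gaussian covariance built by first-order propagation of
  the independent measurement errors through the whole residual
  y − λ̂(estimates), including the self-term 1 − ∂λ̂/∂λ_obs. A toggle
  reduces this to fitness SEs only.

Predictions of extinction for strains observed growing contribute a finite
penalty (default 10³ per point) so optimization remains well-behaved near
the cliff. The search is a deterministic coarse grid over
(c_δ, c_T, c_C) ≥ 0 followed by Nelder-Mead refinement, and the returned fit
carries a score grid over (c_T, c_C) at the ML c_δ for model comparison;
nested constrained fits (e.g. c_C = 0) give score deltas that are
non-negative by construction.

**Identifiability.** With conditions at 0 and 1 mM only, c_T and c_C act on
nearly collinear combinations (they separate only through the 1/λ² spread
across strains), so their individual estimates trade off against each other
while c_δ and c_C remain recoverable; the dose-response design option
improves the separation. The 2-score-unit region of the (c_T, c_C) grid at
the ML c_δ is a conditional slice, not a profile: it does not re-optimize
c_δ, and c_δ is pinned at 0 mM by the few constitutive-like strains alone.
Its frequentist coverage of the true pair is therefore noticeably below the
nominal χ²₂ value (86.5%) — the acceptance script reports the observed
fraction across seeded panels rather than assuming it.

## Synthetic data

The generator emulates the study design: 12 operator mutants (the first
pinned to the wild type, δ_max = 1, χ₀ = 10⁻³; the rest log-uniform in
δ_max over [0.2, 3] with half sharing the wild-type χ₀ and half log-uniform
in [10⁻³, 0.5]), a ΔlacI constitutive strain, a ΔlacY pumpless constitutive
control and the lac-deleted reference; conditions 0 and 1 mM IPTG (plus an
optional dose-response grid); 12 fitness and 3 concentration replicates with
Gaussian noise (fitness SD 0.025; concentration SD 0.002 + 0.05·truth —
stylized magnitudes producing standard errors of the size competition and
Miller assays report, not measured values). Truths come from the model's
stable fixed point; conditions beyond a strain's cliff are excluded with a
warning (optionally retained as censored rows). The competition-assay
simulator starts both strains at 5×10⁴ CFU, grows the reference ~13
doublings (to saturation of a 24 h culture) and Poisson-samples counts, with
fitness estimated as λ = ln(Xf/Xi)/ln(Yf/Yi).

What the generator does **not** emulate: day effects or any correlated
assay noise beyond the replicate structure, non-Gaussian tails, plating
detection limits (concentration replicates may go slightly negative at the
assay floor, as background-subtracted Miller assays do), sequence-level
operator structure, and any fitness benefit of the transported sugar.
Passing tests therefore demonstrate correctness of the machinery under the
stated noise model, not agreement with any particular experimental dataset.

## Problem sizes and determinism

All randomness flows from explicit seeds (a single top-level seed in the
pipeline). The test suite uses 1000 random draws for closed-form limits, 100
draws against a 10⁵-point scan oracle, 10⁵ Monte-Carlo resamples for error
propagation, and 20 seeded panels for coefficient recovery; the acceptance
script uses 50 oracle draws and 10 recovery panels. These sizes were chosen
to make the checked properties statistically meaningful while keeping a full
run fast on a laptop.

## Known limitations

- No mechanistic intracellular inducer model: induction acts through the
  external concentration, and no lactose-benefit term is included.
- The growth-expression coupling η is a stylized quadratic-times-linear form
  (exact under the stated dilution/volume/concentration laws) clipped at 0
  for fast growth; θ defaults to 0.
- Three or more fixed points cannot arise in the polynomial (θ = 0) regimes
  but are not excluded a priori for θ > 0; the solver reports all roots with
  a warning in that case.
- The likelihood treats strains as independent blocks; shared systematic
  errors across strains (e.g. a miscalibrated inducer stock) are not
  modeled.
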