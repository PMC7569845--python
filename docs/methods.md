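# Methods

## Model and assumptions

The package models bulk erosion of a single PLGA microsphere through one
scalar state, the soluble-product mass fraction μ_S ∈ [0, 1), with the
residual polymer fraction μ_P = 1 − μ_S and the nondimensional front radius
R_f = μ_S^{1/3}.

The rate law comes from treating hydrolysis as an enzyme-like scheme — the
soluble acid A attacks intact polymer P through a partially degraded
complex AP which releases soluble products S — and applying the
quasi-steady-state approximation. In nondimensional variables this
collapses to

dμ_S/dt = B₀ (1 − μ_S) / (1 + Ψ ω_P − μ_S) · s(t),  μ_S(0) = 0,

where ω_P(t) = exp(−k_deg t) is the nondimensional molecular weight
(first-order chain scission, evaluated analytically inside the right-hand
side rather than integrated as a second state) and
s(t) = [tanh(α(t − t_ind)) + 1]/2 is a mollified Heaviside switch encoding
the induction lag before chains fall below the solubility threshold.

Assumptions inherited by everything downstream:

* no swelling — the particle radius is constant, so the volume balance
  μ_P = 1 − R_f³ converts mass fractions to front radii;
* the molecular weight of soluble products is constant, and a single
  overall k_deg describes chain scission;
* the encapsulated protein's mass (≈0.25 % of the particle) is neglected
  in the mass balance — three orders of magnitude below measurement noise;
* degradation is spatially lumped: the front radius is a bookkeeping
  variable derived from μ_S, not a reaction–diffusion solution.

The two lumped parameters reduce from dimensional quantities as
B₀ = V_MS·MW_S·R₀/m_MS,0 and Ψ = K_M·V_MS·MW_P,0/m_MS,0
(`PhysicalParams` / `derive_b0_psi`); simulating with derived values is
bit-identical to simulating with the lumped values directly.

## Parameters, units, defaults

| name  | meaning                            | unit  | default / preset range |
|-------|------------------------------------|-------|------------------------|
| B₀    | initial degradation rate           | 1/day | 0.0248–0.0346          |
| Ψ     | acid–polymer affinity              | –     | 1.6e-5–4.3e-5          |
| t_ind | induction time                     | day   | 2.91–3.42              |
| k_deg | molecular-weight decay constant    | 1/day | 0.0997–0.104           |
| α     | induction-switch sharpness         | 1/day | 2.5 (fixed)            |
| dt    | RK4 step                           | day   | 0.05                   |

α is exposed but excluded from fitting. The three presets (`PLGA10`,
`PLGA15`, `PLGA20`) carry the published best-fit constants for the 10/15/20
% w/v formulations together with their mean particle radii (12.15, 11.5,
12.05 µm); they define the ground truth for all recovery studies. Time is
measured in days throughout.

## Numerical choices

* **Integrator.** Fixed-step classical RK4; the brace in the rate law is
  read so that the switch is (tanh+1)/2, the only reading that reduces to
  the sharp Heaviside dynamics as α → ∞. With B₀ ≈ 0.03 day⁻¹ the system is
  non-stiff at dt = 0.05 day; dt = 0.1 vs dt = 0.001 agree to ~1e-8 in
  sup-norm, and the solution matches scipy's adaptive RK45 at rtol 1e-10 to
  better than 1e-6. The final step is shortened to land exactly on t_end.
* **Clamping.** μ_S → 1 is an asymptote approached very sharply once
  1 − μ_S ~ Ψω_P, where the local decay rate B₀/(Ψω_P) far exceeds 1/dt;
  RK4 can overshoot by up to ~1e-3 there. After each step the state is
  clamped to [0, 1] and excursions above 1e-9 are logged (silenced inside
  optimizer loops, where trial parameter sets overshoot routinely).
  Intermediate RK4 stages are clamped at 1 as well so the denominator stays
  positive.
* **Heaviside variant.** `integrate_rk4(..., switch="heaviside")` uses the
  sharp step (H(0) = ½ to match the mollifier's midpoint). Comparisons with
  the α → ∞ limit are made at dt = 0.001: with a discontinuous right-hand
  side the RK4 quadrature error across the switching step is O(rate·dt),
  so coarse steps would dominate the comparison.
* **k_deg estimators.** Default is log-linear regression of ln ω_P on t
  through the origin — closed-form and exact for noise-free or
  multiplicative-error decay. Under *additive* Gaussian noise it is
  strongly biased once the decayed tail is comparable to the noise sd (the
  log transform inflates near-floor values): at sd 0.02 on a weekly 0–42 d
  schedule the bias is ≈ +24 %. The raw-scale nonlinear estimator
  (`method="nls"`) is unbiased there (≈0.4 %), so `recovery_study`
  auto-selects it whenever noise_sd > 0.
* **Front fit.** Bounded least squares (scipy `least_squares`, trf) over
  B₀ ∈ (0, 1], Ψ ∈ [0, 1], t_ind ∈ [0, max t], squared loss, no weighting.
  Multi-start initialisation: B₀ and Ψ log-uniform over [1e-3, 1e-1] and
  [1e-7, 1e-3], t_ind uniform over [0, 10] d, all from one seeded
  generator; objective tolerance 1e-10, ≤500 evaluations per start. The
  best start is polished once with per-parameter scaling
  x_scale = (1e-2, 1e-5, 1) and tight xtol, which is what pins Ψ in
  noise-free round trips despite its shallow objective direction.
* **Degenerate inputs.** An all-zero front series is returned immediately
  with B₀ at the zero boundary and Ψ, t_ind flagged non-identifiable; an
  optimizer run would only wander a flat objective.
* **Spread.** Mirroring how repeat-based SDs are reported for this kind of
  fit, per-parameter spread is the SD across per-replicate refits when ≥2
  replicate series are supplied, else across converged multi-start
  solutions; the mode used is recorded on the result.

## Identifiability

Ψ at its realistic magnitude (~1e-5) is weakly identified: multiplying it
by 10 moves the noise-free front curve by <1e-3 in sup-norm, because the
Ψω_P term only matters in the brief interval where 1 − μ_S has decayed to
its scale. Noise-free round trips still recover it (residuals vanish
exactly at the truth), but any measurement noise produces order-of-magnitude
scatter — consistent with published spreads for this parameter exceeding
the estimate itself. Results objects therefore always list `psi` under
`weakly_identified`. B₀ and t_ind are strongly identified (≤1 % noise-free,
a few % at 2 % noise).

## Synthetic data

The generator emulates the two assays from a preset: gravimetric mass
fractions (lost or residual view) and GPC nondimensional molecular weight,
on a default schedule of days {0, 1, 3, 7, 10, 14, 21, 28, 35, 42} spanning
the 0–6-week window of such studies. Noise is additive Gaussian on the
measured scale — sd 0.02 for mass fractions (gravimetric assays of this
kind validate to a few percent) and 0.03 for ω_P — truncated to the
physical range ([0, 1], respectively ≥1e-6 so log-scale fits stay
defined). Replicates share the model curve and differ only in their noise
stream; outputs are byte-identical for identical seeds. A convenience
generator perturbs the derived front radius directly for recovery studies
phrased on the R_f scale.

What the generator does **not** emulate: systematic gravimetric bias
(incomplete polymer recovery), heteroscedastic or correlated GPC errors,
particle-size polydispersity, or inter-batch variation of the true
constants. Passing recovery tests therefore demonstrate estimator
correctness under the model's own assumptions, not robustness to real-data
pathologies.

## Problem sizes

Recovery studies in the tests and the acceptance script use 15-point front
curves over 0–42 days and weekly molecular-weight series; noise-free round
trips use 10 multi-starts, Monte-Carlo studies 20 replicates × 3 noise
levels with 3 starts per fit. These sizes match the sampling density of the
emulated experiments while keeping a full study run in well under a minute.

## Known limitations

* The front radius is meaningful only under the constant-radius,
  uniform-density assumptions; formulations that swell or fragment violate
  the volume balance.
* k_deg and the front parameters are fitted independently, as in the
  source procedure; a joint fit (and any error-in-variables treatment of
  the ω_P series) is out of scope.
* The fixed-step integrator is appropriate for the non-stiff parameter
  regime of the presets; pathological parameter sets (B₀ ~ 1, Ψ ~ 1) would
  warrant a smaller dt than the default.
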