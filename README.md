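# erokin

Kinetics of autocatalytic bulk erosion in protein-loaded PLGA microspheres:
forward simulation, synthetic assay data, and least-squares parameter
inference.

## The problem

Poly(lactic-*co*-glycolic acid) (PLGA) microspheres are a standard vehicle
for controlled protein delivery. The polymer hydrolyses at its ester bonds;
the acidic fragments trapped inside the particle lower the local pH and
accelerate further hydrolysis (autocatalysis), so degradation runs fastest
at the core and a solubilised region grows outward behind a moving
*degradation front*. Formulators want the few constants that summarise this
process for a given formulation, estimated from the two assays a
degradation study actually produces:

* **gravimetric mass loss** — the residual polymer fraction over weeks of
  immersion, and
* **GPC molecular weight** — the number-average polymer molecular weight,
  normalised to its initial value.

`erokin` implements the lumped kinetic model for these data, a synthetic
generator that emulates both assays, and the two-stage fitting procedure
that recovers the constants.

## The model

Let μ_S(t) be the soluble-product mass fraction (μ_P = 1 − μ_S the residual
polymer fraction), and ω_P(t) = MW_P(t)/MW_P(0) the nondimensional
molecular weight. Chain scission is first order,

    ω_P(t) = exp(−k_deg · t),

and the soluble fraction obeys a Michaelis–Menten-like rate law gated by a
mollified induction switch:

    dμ_S/dt = ½ · B₀ (1 − μ_S) / (1 + Ψ ω_P − μ_S) · [tanh(α(t − t_ind)) + 1],
    μ_S(0) = 0.

Parameters: B₀ (day⁻¹) the lumped initial degradation rate, Ψ (–) the
acid–polymer affinity (small Ψ ⇒ stable acid–polymer complex), t_ind (day)
the induction lag before soluble oligomers appear, k_deg (day⁻¹) the
molecular-weight decay constant, and α (day⁻¹, fixed at 2.5) the switch
sharpness. Since the eroded core is a sphere, the nondimensional front
radius follows from the volume balance μ_P = 1 − R_f³:

    R_f(t) = μ_S(t)^(1/3).

The ODE is integrated with a fixed-step classical Runge–Kutta (RK4)
scheme. Inference is two-stage, as in practice: k_deg is fitted to the GPC
series first (closed-form log-linear fit, or raw-scale nonlinear least
squares for noisy data), then (B₀, Ψ, t_ind) are fitted to the front-radius
series by bounded multi-start least squares with k_deg held fixed. Ψ is
weakly identifiable at realistic magnitudes (~10⁻⁵) and is flagged as such.

Three formulation presets (`PLGA10`, `PLGA15`, `PLGA20` — 10/15/20 % w/v
polymer in the emulsion organic phase) carry the published best-fit
constants and serve as ground truth for recovery studies.

## Worked example

```python
import numpy as np
import erokin as ek

p = ek.get_preset("PLGA15")
t = np.linspace(0, 42, 15)

# synthetic experiment: 3 noisy front-radius replicates + one GPC series
series = ek.generate_front_series(p, t, noise_sd=0.02, n_replicates=3, seed=11)
mw = ek.generate_mw_series(p, np.arange(0, 43, 7.0), noise_sd=0.03,
                           n_replicates=1, seed=11)[0]

kres = ek.MolecularWeightDecay(mw).fit(method="nls")
res = ek.DegradationFrontModel(series, k_deg=kres.k_deg).fit(n_starts=6, seed=0)
print(res.summary())
```

prints

```
Degradation-front kinetics fit
====================================================
n obs: 45   starts: 6   spread over: replicates
k_deg fixed at 0.0943057 /day, alpha = 2.5 /day
----------------------------------------------------
B0    [1/day]: 0.0266503  (sd 0.0018)
psi   [-]:     2.21041e-25  (sd 0.103)
t_ind [day]:   3.30355  (sd 0.132)
----------------------------------------------------
SSR: 0.0118101   converged: True
weakly identified: psi
```

With 2 % noise the strongly identified constants land close to the
generating preset (B₀ = 0.0272 day⁻¹, t_ind = 3.40 day), while Ψ collapses
to the boundary — the expected signature of its weak identifiability; its
spread across replicates is correspondingly wide. `res.plot()` overlays
data and fitted curve; `res.predict(times)` evaluates the fitted front.

The same pipeline is available from the shell:

```sh
erokin synth --preset PLGA15 --kind front-radius --noise-sd 0.02 \
             --replicates 3 --seed 11 --out front.csv
erokin fit-front --data front.csv --k-deg 0.0997 --seed 0 --out fit.yaml
erokin simulate --preset PLGA20 --t-end 42 --out curve.csv
erokin recover --preset PLGA15 --noise-sd 0.02 --n-reps 20 --seed 7 --out rec.csv
```

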