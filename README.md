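# mnasim

Column-to-site modelling of **monitored natural attenuation (MNA)** of
1,1,1-trichloroethane (TCA) in shallow groundwater.

Chlorinated-solvent plumes are often managed by relying on intrinsic
sorption and microbial dehydrochlorination rather than active remediation.
Deciding whether that is defensible requires (i) a transport model of the
laboratory column experiments that mimic the aquifer, (ii) estimates of the
sorption and first-order biodegradation parameters from paired
biotic/sterile breakthrough curves, and (iii) a site-scale forecast of the
plume under the estimated kinetics.  `mnasim` implements that whole chain
for hydrogeologists and environmental engineers, together with a
synthetic-data generator that stands in for unpublished laboratory and
field measurements so every stage is testable end to end.

## The model

One-dimensional saturated column transport follows the
advection–dispersion–reaction (ADR) equation with linear kinetic sorption
and first-order aqueous decay,

```
θ ∂c/∂t = ∂/∂x(θD ∂c/∂x) − q ∂c/∂x − ρ_b ∂s/∂t − θ k c
ρ_b ∂s/∂t = ρ_b α (K_d c − s)
```

with `c` aqueous concentration (mg/L), `s` sorbed concentration (g/kg),
`θ` porosity, `ρ_b` bulk density, `q = θv` Darcy flux, `D = α_L v` the
hydrodynamic dispersion, `K_d` the linear sorption coefficient, `α` the
sorption rate and `k` the dehydrochlorination rate.  With
`α → ∞` the model reduces to the retarded ADR with
`R = 1 + ρ_b K_d / θ`.  The solver is a conservative finite-volume
Crank–Nicolson scheme with a third-type (flux) inlet and a
zero-dispersive-gradient outlet, verified against the closed-form
constant-injection solutions (resident and flux-averaged detection modes).

Calibration mirrors the experimental design: the conservative NaCl tracer
fixes the hydrodynamics (`TracerModel`), the sterile control column fixes
`K_d` (`SorptionModel`), and the biotic column, with sorption frozen,
fixes `k` (`DecayModel`).  Each `fit()` returns a results object with the
point estimate, objective, optimizer trace, a `summary()` table, and
optional residual-bootstrap confidence intervals.  At the site scale a
steady finite-difference groundwater flow solve (`solve_steady_flow`)
drives a 3-D upwind transport forecast (`simulate_plume`) with equilibrium
retardation and aqueous decay and no persistent source, so total plume
mass decays as `M₀ exp(−kt/R)`.

## Worked example

Generate a noisy synthetic twin of the paired-column experiment and invert
it (shell interface; the same operations are available as library calls):

```sh
mnasim make-synthetic --out run1 --seed 7
mnasim fit-params --control run1/btc_control.csv --biotic run1/btc_biotic.csv \
    --truth run1/truth.json --out fit1 --seed 7
mnasim fit-tracer --tracer run1/tracer_col1.csv --out fit2
```

The calibration prints (seed 7, 5 % measurement noise):

```
Column calibration
  free parameter : decay
  sorption coeff : 7.321670791387185e-05 m^3/kg
  sorption rate  : 0.1 1/d
  decay          : 0.004883754771122416 1/d
  objective (SSR): 13.0966 (mg/L)^2
  converged      : True
Conservative tracer fit
  dispersivity      : 0.00515595 m
  effective porosity: 0.292239
  mean residence    : 4.782 d
```

The generating truths were `K_d = 6.8e-5 m³/kg`, `k = 0.0045 d⁻¹`,
dispersivity `0.005 m`, porosity `0.296`: with one noisy 13-sample curve
per column the sorption coefficient comes back within ~8 %, the decay rate
within ~9 %, and the tracer hydrodynamics within a few percent — the
scatter expected from the measurement noise, quantifiable via
`--bootstrap 200`.  `mnasim simulate-site` then forecasts the synthetic
plume (anchored at 49.70, 22.00 and 0.297 mg/L monitoring wells on a
100 m × 100 m, four-layer grid): under the calibrated kinetics the
≥ 25 mg/L source area disappears within roughly a year and the maximum
concentration falls below the 0.3 mg/L intervention value by year five.

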