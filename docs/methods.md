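# Methods

## Scope and model chain

`mnasim` models natural attenuation of 1,1,1-trichloroethane (TCA) at
three linked scales: a 1-D packed-column transport model, least-squares
calibration of its sorption and degradation parameters from paired
breakthrough curves (BTCs), and a 3-D site-scale flow and transport
forecast.  A synthetic-data module generates every input from the
documented study conditions, because no laboratory or field measurements
are published for this system.

## Column transport model

Governing equations (units: m, d, mg/L ≡ g/m³, kg/m³, g/kg):

    θ ∂c/∂t = ∂/∂x(θ D ∂c/∂x) − q ∂c/∂x − ρ_b ∂s/∂t − θ k c
    ρ_b ∂s/∂t = ρ_b α (K_d c − s)

Assumptions: saturated, isothermal, single-species transport; linear
sorption with first-order kinetics (one-site); degradation acts on the
aqueous phase only, consistent with the plateau balance used for the
closed-form cross-check (see below).  The equilibrium limit
(`sorption_rate = EQUILIBRIUM`) collapses to the retarded ADR with
R = 1 + ρ_b K_d/θ.  Daughter products (1,1-DCA, CA) are not modelled.

### Numerics

Cell-centred finite volume, Crank–Nicolson in time, with the kinetic
sorbed phase eliminated algebraically each step so the update is one
tridiagonal solve per step (exactly conservative; the internal mass ledger
closes to machine precision).  Inlet is third-type (prescribed total flux
`v·C0(t)`), outlet has zero dispersive gradient (Danckwerts).  Advection
uses central face interpolation when the face Peclet number `v Δx/D ≤ 2`
and first-order upwinding otherwise ("hybrid", the default): at the grids
used here (Δx ≈ 0.75–3 mm against a dispersive front several cm wide)
upwinding alone would add numerical dispersion of order 5–10 % of the
physical `D`, which is why the hybrid default was chosen over
always-upwind.  Defaults: `nx = 200`, `Δt = 0.5 Δx/v` (Courant 0.5);
Crank–Nicolson is A-stable, so coarser fixed steps (`dt = 0.05 d`) are
used in fitting-heavy tests with ~0.1 % effect on the BTC.  Instability
guards: non-finite values raise immediately; any effluent below
`−10⁻⁹ C0` raises; smaller negative round-off is clipped.

### Analytic oracles and detection mode

`analytic_ade` implements the constant-injection solutions of the retarded
ADR with first-order decay on a semi-infinite domain with the same
third-type inlet, in two detection modes.  The *resident* mode is the
volume-averaged concentration; the *flux* mode is `c − (D/v) ∂c/∂x`, which
is what an effluent sample physically measures (for a flux-type inlet it
coincides with the resident solution of the first-type-inlet problem).
Effluent BTCs must be compared in flux mode: the resident profile lags the
measured effluent by about `R D/v²` (~0.12 d here, a 1.3 % L2 discrepancy
that the flux mode removes to < 0.1 %).  Degenerate-decay arguments
(4kD/v² < 1e−12) fall back to the conservative forms to avoid
cancellation; large-argument products `exp(a)·erfc(b)` are evaluated via
`erfcx`.

The plug-flow steady-state ratio `exp(−k t_res)` provides an independent
scalar cross-check; dispersion corrections to it are O(kD/v²) ≈ 4e−4 and
ignored.

## Study conditions (generator defaults)

Two 30 cm × 10 cm columns: porosity 0.296 (biotic #1) / 0.289 (sterile
control #2), bulk density 1850 / 1880 kg/m³, giving pore volumes
697 / 681 cm³; flow 0.1 mL/min (residence times 4.84 / 4.73 d); influent
31.36 ± 1.87 mg/L TCA, one reservoir draw per experiment; 13 effluent
samples every 2 d ending at 25 d (≈ 5.16 pore volumes on column #1);
measurement noise additive Gaussian, s.d. 5 % of the influent mean
(comparable to the reported influent spread 1.87/31.36 ≈ 6 %), truncated
at zero.  Tracer: 3 g/L NaCl step over 3 pore volumes, sampled every
0.1 PV (conductivity-probe resolution, denser than the syringe sampling of
the solvent).  Dispersivity default 0.005 m (≈ L/60, typical of repacked
laboratory columns).

**Sorption coefficient units.**  The calibrated sorption coefficient is
carried as 6.8e−5 m³/kg (0.068 L/kg).  Taken literally as 0.068 m³/kg the
coefficient would imply R ≈ 426 (equilibrium) or an initial kinetic
sorption sink of ~42 d⁻¹, and the sorbed front would penetrate only a few
millimetres in 25 days — no breakthrough would occur within the
experiment, contradicting the observed curves and the stable plateau in
the 4.75–5.16 PV window.  At 0.068 L/kg, R ≈ 1.43 and breakthrough
completes within ~2 PV, consistent with both.  The value is configurable;
the package is self-consistent under either reading.

**Kinetic sorption rate.**  α defaults to 0.1 d⁻¹, a relaxation time of
10 d: slow enough to matter over the 25-d experiment (the control column
still shows a ~2 % sorption transient at day 25), fast enough not to
suppress breakthrough.  Computations that represent the *stabilised*
plateau (the steady-window biotic-vs-control difference) use the
equilibrium limit instead, since the plateau comparison presumes the
sorption transient has died out.

**Decay.**  Calibrated k = 0.0045 d⁻¹ with plausible range
0.003–0.006 d⁻¹.  At these values the influent–effluent plateau difference
between the columns is 31.36·(1 − exp(−0.0045·4.84)) ≈ 0.68 mg/L.

## Calibration

Order mirrors the experiment: tracer → sorption (sterile control, decay
fixed at 0) → decay (biotic, sorption frozen).  The objective is
unweighted least squares on concentrations.  Scalar parameters are
minimised by bounded Brent searches over log-spaced sub-intervals (3
starts by default) plus an explicit probe of the zero endpoint; ties break
toward the smaller parameter.  A flat objective (spread < 1e−10 of its
scale) raises an identifiability warning.  The tracer fit is a 2-parameter
`least_squares` over (dispersivity, porosity), started from temporal
moments; its forward model defaults to the numerical finite-column solver
because the semi-infinite analytic solution mis-attributes the outlet
boundary effect to dispersivity at the ~1.7 % level.

Noisy-replicate calibrations use each replicate's recorded true influent
concentration (the generator serialises truth beside every dataset).  The
per-refill influent draw has s.d. ~6 % of C0 while the decay signal is a
~2 % effluent depression; fitting against the nominal mean influent would
measure reservoir variability, not k.

Uncertainty: residual-resampling percentile bootstrap (≥ 50 replicates
enforced, deterministic under a fixed seed).  The reported 0.003–0.006
range for k is treated as a plausible interval; the bootstrap here is the
package's own uncertainty method, not a reconstruction of how that range
was first obtained.

Estimator properties worth knowing: with 13 samples and 5 % noise the
single-experiment decay estimate has s.d. ≈ 0.003 d⁻¹ (the median of 20
replicates, s.d. ≈ 0.0008 d⁻¹, is the quantity checked against the
range); the single-replicate tracer dispersivity has s.d. ≈ 7 % at 2 %
noise, so unbiasedness tests average several replicates.

## Site model

Grid: 100 m × 100 m, Δx = Δy = 1 m, four 2-m layers (0–8 m depth, wells
screened 2–8 m).  Flow: ∇·(K∇h) = 0 with harmonic-mean interface
conductivities, constant-head cells on the west/east faces (default heads
10.0/9.8 m, hydraulic gradient 0.002 — a "low slope" regime), no-flow
elsewhere; solved sparse-direct.  Horizontal K defaults to 10× the
measured vertical conductivity (2.25e−7 m/s → K_h ≈ 0.19 m/d), a standard
anisotropy assumption; porosity 0.296 as measured on the aquifer soil.
None of the boundary heads, layer thicknesses, anisotropy or site
dispersivities are reported for the real site; all are configurable
defaults chosen to be hydrogeologically unremarkable.

Transport: explicit upwind advection and explicit velocity-dependent
dispersion (α_L = 1 m, α_T = 0.1 m defaults) with sub-stepping to Courant
≤ 0.9 and the diffusive stability limit; site-scale sorption enters as an
equilibrium retardation factor (the forecast horizon of years makes the
10-d sorption kinetics irrelevant); aqueous decay is applied analytically
per sub-step, so in a closed domain total mass follows M₀ exp(−kt/R)
essentially exactly.  Constant-head cells exchange water with the outside:
inflow enters clean, outflow leaves at the cell concentration.  No
persistent source term: the forecast describes attenuation of the June-2007
plume, not continued DNAPL dissolution — a deliberate scope limit.

The synthetic initial plume is a sum of Gaussian kernels (8 m horizontal,
2 m vertical scale) with weights solved exactly so the anchor wells
(MW-3 49.70 mg/L at 2–4 m, MW-5 22.00 mg/L at 4–6 m, MW-104 0.297 mg/L)
are reproduced at their cells; well coordinates on the grid are nominal.
The kernel surface is a plausible stand-in, not an estimate of the real
plume's spatial correlation.  Consequently the site-scale outputs
(well-wise MSE, plume areas, the ~1-year disappearance of the ≥ 25 mg/L
source area, the sub-0.3 mg/L maximum at 5 years) validate the machinery
and the kinetics on a synthetic twin; they are not reproductions of the
field-calibrated numbers, which would require the unpublished monitoring
data.

## Degenerate inputs and tie-breaks

Zero porosity, non-positive dimensions, non-contiguous inlet schedules,
negative concentrations and reversed intervals are rejected at
construction.  Equal plateau concentrations give k = 0 exactly; a biotic
plateau above the control raises a sign warning (no degradation signal);
a vanishing biotic concentration raises an overflow error rather than
returning infinity.  Threshold metrics are inclusive (a cell exactly at
25 mg/L counts); plan-view area is the footprint of the layer-maximum
field times Δx·Δy.

## Problem sizes

The defaults above are full scale.  The test suite runs the column solver
at nx = 48–150 with fixed Crank–Nicolson steps and the site solver on
reduced grids (e.g. 40 × 30 × 2), sizes at which every checked property
(oracle agreement < 1 %, mass closure < 0.1 %, parameter recovery) already
holds with wide margin; the acceptance script uses the spec-default
nx = 200 column grid.  The bootstrap-coverage check runs at reduced
replicate counts and is a smoke test of calibration, not a precise
coverage estimate.

## Known limitations

Single species (no DCA/CA chain); no transient flow, recharge, pumping or
perched-water effects; no DNAPL dissolution source; linear sorption only;
conductivity–concentration calibration is linear (adequate below ~5 g/L
NaCl).  The decay rate is identified from a ~2 % effluent depression, so
its single-experiment uncertainty is large by construction — this is a
property of the experimental design the synthetic twin reproduces, not of
the estimator.
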