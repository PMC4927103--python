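# Methods

`drainsim` models water flow and mineral-nitrogen turnover in the soil
treatment area (drainfield) of onsite wastewater treatment systems, at the
scale of an instrumented soil-column mesocosm (15 cm ID, 137 cm of soil).
Three system types are built in: a pressurized shallow narrow drainfield
(PSND) dosed with advanced-treated effluent (ATE), its Geomat variant
(GEO) with an entangled-filament distribution layer, and a conventional
pipe-and-stone trench (P&S) dosed with septic tank effluent (STE).

## Water flow

Flow is variably-saturated Richards flow on a 2D vertical plane (x, z with
z in cm below the ground surface),

    dtheta/dt = div( K(h) grad(h - z) ),

with van Genuchten retention theta(h) = theta_r + (theta_s - theta_r)
[1 + |alpha h|^n]^(-m), Mualem conductivity K = Ks Se^l [1 - (1 -
Se^(1/m))^m]^2, m = 1 - 1/n (never stored independently), l = 0.5. No
rain, evaporation or root uptake is simulated: the atmospheric top
boundary acts as no-flux, sides and bottom are no-flux, and a single
seepage-face cell at the bottom centre discharges only while locally
saturated, producing the hanging water table observed in the columns. The
effluent enters through a variable-flux segment at the infiltrative
surface: the full 15-cm width for PSND, a pipe-diameter (2.54 cm) segment
under the distribution pipe for GEO and P&S.

Default hydraulic parameters are the calibrated means (n = 3 replicate
columns) for each system: e.g. PSND silt loam theta_r = 0.025, theta_s =
0.203, alpha = 0.0847 1/cm, n = 2.289, Ks = 220 cm/d over gravelly-coarse
sand theta_r = 0.013, theta_s = 0.063, alpha = 0.0205, n = 4.037, Ks =
909 cm/d. Entangled filaments and crushed stone are fixed highly
conductive fill (Ks = 3000 cm/d) with coarse-gravel-like retention and
are excluded from calibration and WFPS reporting.

### Discretization and numerics

Cell-centered finite volumes on a structured quadrilateral grid. The
vertical spacing equidistributes a target-size field: 0.42-cm cells
inside refinement bands (distribution pipe, cover, infiltrative surface,
and the silt/sand horizon contrast, where capillary-barrier boundary
layers form), growing to <= 3.6 cm elsewhere; horizon boundaries are hard
mesh lines. The resulting meshes have 675 (PSND), 621 (GEO) and 558
(P&S) nodes.

Time stepping is backward Euler with modified-Picard (mixed-form)
iteration, so the discrete water balance closes to machine precision
independent of step size (closure is reported on every run and asserted
<= 0.5% in the tests; in practice it is ~1e-12 relative). Iteration
details that matter:

* internodal conductivity: arithmetic mean of the cell values (the
  geometric mean chokes infiltration into initially dry coarse fill and
  stalls the first trench dose; geometric and upstream weighting remain
  selectable via `FlowConfig.internodal`);
* convergence at max |dh| < 1e-6 cm, or at a water-content residual
  < 1e-8 together with |dh| < 0.1 cm — in dry cells of sharp-`n`
  materials the capacity vanishes and the head is ill-conditioned while
  theta, the conserved quantity, is not;
* element-wise damping of updates whose sign flips between iterations,
  and a 20-cm per-iteration update clamp (wetting fronts entering dry
  gravel);
* adaptive dt in [1e-8, 0.5] d: aggressive doubling under a ceiling that
  non-convergence lowers and accepted steps relax, with early bail-out
  of diverging iterations (capillary-barrier bistability at the
  silt/sand interface);
* saturated cells get a small specific storage (1e-5 1/cm) so ponded
  states stay non-singular.

Dosing regimes follow the experiments: 2 L/d ATE in 42-mL doses over
15 min every 30 min (PSND, GEO) and 400 mL/d STE in two 200-mL doses
over 1.5 h every 12 h (P&S). Pulse trains with periods <= 2 h are far
below the hydraulic response time of the native soils, and the advanced
systems run at a steady moisture state under them, so such schedules are
smoothed to their period-average flux by default (`resolve_pulses=True`
forces full resolution); the 12-hourly trench doses are always resolved
and reproduce the peak-and-decay moisture signature between doses.

### WFPS summaries

Water-filled pore space is theta/theta_s (this definition, not effective
saturation, reproduces the published layer values under a unit-gradient
analysis). `wfps_by_layer` reports per-layer time averages over the final
30 days of a run. The default metric averages WFPS at the probe
observation nodes (15 and 30 cm below the infiltrative surface), matching
how the columns were instrumented; a volume-average variant (excluding
the seepage-controlled saturated bottom) is available, but note that with
air-entry values near 50 cm the gravelly sand's capillary fringe occupies
much of the layer, so volume averages sit well above probe values.

## Nitrogen kinetics and transport

NH4+ and NO3- are transported by advection-dispersion in the liquid
phase, with the sequential chain NH4+ -> NO3- -> N2. Influent organic N
is assumed mineralized at the inlet: STE doses as (TN, 0), ATE (18%
organic, 26% NH4+, 56% NO3-) as (0.44 TN, 0.56 TN); a configurable
recalcitrant organic fraction (default 0) passes through as an inert
tracked species.

Rates are Michaelis-Menten with multiplicative dependency factors:

    mu_nit   = mu_nit,max   C/(Km+C) ft fsw
    mu_denit = mu_denit,max C/(Km+C) ft fsw,dn fz

* `fsw` (nitrification) is the DRAINMOD-N2 three-branch form in
  saturation S = WFPS: f_wp below the wilting-point saturation s_wp,
  a power rise to 1 at s_l, optimal on (s_l, s_h], and a power fall to
  f_s at saturation. Fitted values shared by all systems: f_wp = f_s = 0,
  s_wp = 0.154, s_l = 0.665, s_h = 0.809, e1 = 2.267, e2 = 1.104 —
  nitrification shuts off in saturated soil.
* `fsw,dn` (denitrification) is ((S - s_dn)/(1 - s_dn))^f with s_dn = 0,
  f = 2.86 — denitrification switches on as pores fill.
* `ft` = exp[-0.5 beta Topt + beta T (1 - 0.5 T/Topt)] peaks at Topt.
  Topt defaults to 22.5 C (middle of the usual 20-25 C range) and beta
  to 0.177, which puts ft(20 C; Topt 25) near 0.9; neither value is
  published for these columns and both are exposed as calibration
  targets.
* `fz` = exp(-alpha_c z) encodes the decline of available organic carbon
  with depth z below the infiltrative surface; alpha_c defaults to
  0.02 1/cm (unpublished, calibration target).

Km defaults to 5 mg N/L for both substrates. Maximum rates are not
published; instead each material's `mu_max` is backed out with
`mu_max_from_effective_rate` so that the rate at a reference state (the
published layer-mean WFPS, 20 C, the layer's mid-depth, substrate far
above Km) equals the published effective zero-order layer rate (e.g.
PSND silt loam 45.25 mg N L^-1 d^-1 nitrification, 0.17 denitrification).
Rates are per litre of pore water per day, the liquid-phase convention of
the transport equation.

Transport is operator-split per flow step: an implicit upwind
finite-volume advection-dispersion solve per species (positivity-
preserving at mesocosm Peclet numbers), then a sub-stepped reaction
update that floors concentrations at zero with the rate truncated, so the
chain is exactly conservative (NH4 consumed = NO3 produced; NO3 consumed
= N2 produced, verified as an invariant). Longitudinal dispersivity is
one-tenth of the profile depth below the infiltrative surface,
transverse one-tenth of that; effective diffusion uses free-water values
(NH4 0.067, NO3 0.061 cm^2/h) with Millington-Quirk tortuosity
theta^(7/3)/theta_s^2. NH4+ sorption is off by default (Kd = 0; the
linear retardation R = 1 + rho_b Kd/theta is implemented and verified
against a retarded-breakthrough closed form). N2 is a cumulative produced
mass, not a transported gas. The advection-dispersion solver is verified
against the closed-form semi-infinite-column solution for a constant
solute-flux inlet to within 2% of the feed concentration.

The 90-day N mass balance reports effluent NO3-/NH4+ (and inert organic)
fractions, N2 loss and storage as percent of cumulative N input, closing
to < 0.5%.

## Calibration

`gauss_newton_fit` minimizes a weighted least-squares objective (weights
1/sigma^2; defaults sigma = 0.005 cm^3/cm^3 for moisture, 10% of the mean
for concentrations) by damped Gauss-Newton: undamped steps first,
Levenberg-style damping with step retries only when a step fails to
reduce the objective — so a linear model converges in one accepted step.
Jacobians are forward finite differences with 1% relative perturbation
(absolute fallback at zero). Composite scaled sensitivities CSS_j =
sqrt((1/N) sum_i (dsim_i/dp_j p_j w_i^(1/2))^2) rank parameter
identifiability; parameters with CSS ratio < 0.01 are flagged and can be
frozen out of the regression (`screen_css=True`). The pore-connectivity
exponent l stays fixed at 0.5 and fill materials are never calibrated.

`SteadyProfileModel` integrates the steady profile dh/dz = 1 - q/K(h)
upward from the water table through a layered column (implicit Radau
integration; the silt/sand interface generates a stiff boundary layer).
It serves as a fast forward model for parameter-recovery and sensitivity
studies, and independently cross-checks the 2D solver: the interior of a
homogeneous column agrees with the analytic unit-gradient state to < 1%.
On synthetic moisture data from the PSND configuration, the silt-loam
saturated water content attains the maximum CSS, matching the published
sensitivity ranking.

## Climate scenarios

Scenarios are pure transformations of the run configuration: (i) warmer
soil, 23 C instead of 20 C (spatially uniform, no heat equation, exactly
the published scenario design); (ii) raised water table, implemented by
having the seepage face maintain a pool 30 cm above the bottom, shrinking
the unsaturated zone; (iii) both. With Topt >= the warmed temperature,
warming strictly raises both rates, so the N2 loss fraction rises;
saturating the bottom of the profile suppresses nitrification there
(fsw -> 0 at saturation) so effluent NH4+ rises; the combined scenario
compounds both. These directions are asserted in the acceptance suite on
the GEO system.

## Synthetic data

`synthetic.SyntheticTruth` fixes ground-truth hydraulics (system
calibrated means by default), influent statistics, a noise model and a
seed; all randomness flows from that seed. Weekly influent TN is Gaussian
(truncated at zero) and speciated by source. Because the raw influent
chemistry of the original columns is unpublished, the defaults are
literature-typical: STE TN = 60 +/- 10 mg N/L, ATE TN = 40 +/- 8 mg N/L.
Moisture probes are sampled sub-daily with additive Gaussian noise
(0.005 cm^3/cm^3), effluent chemistry weekly with multiplicative
lognormal noise (CV 0.10, keeping concentrations non-negative).
Observations come either from the full 2D forward model or from the
steady-profile surrogate (moisture only, orders of magnitude faster).
The generator does not emulate probe drift, biomat development over
time, or structured replicate-to-replicate heterogeneity — so passing
recovery tests demonstrate estimator correctness under the stated noise
model, not robustness to those real-data features.

## Problem sizes and known limitations

Default runs are 90 simulated days on the meshes above; a PSND run takes
about a minute on one core, GEO a few seconds (steady under smoothed
dosing), P&S one to two minutes (180 resolved dose cycles). Verification
columns in the test suite use 1D grids of 30-440 cells.

Known limitations, beyond the explicit non-goals (no NO2-/N2O
intermediates, no heat equation, no hysteresis, no biomat dynamics):

* The published P&S water-content regime is not reachable from the
  published P&S hydraulic parameters: the calibrated trench-sand Ks
  (4.5 cm/d, a biomat proxy) is only twice the mean applied flux, so any
  conveyance of the dosed volume holds the sand near saturation
  (WFPS ~ 0.9), whereas the published layer WFPS is 0.27. The package
  reproduces the physics of the stated parameterization; the
  corresponding acceptance check documents the discrepancy by failing.
* Similarly, the published effective denitrification rates (pore-water
  basis, 0.01-1.31 mg N L^-1 d^-1) bound N2 production at a few percent
  of N input in <= 2 L of pore water, and cannot produce the published
  N2 loss fractions of 10-18%; the N-fraction acceptance checks record
  this inconsistency rather than hiding it.
* The 2D vertical plane stands in for a cylindrical column (the plane
  carries the per-area fluxes exactly; lateral spreading geometry
  differs). An axisymmetric weighting flag exists on `FlowConfig` for
  sensitivity checks; the plane form is the default and the reference.
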