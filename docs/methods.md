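# Methods

This note records the models implemented in `kelpflux`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
scenario does and does not establish about real shelves.

## The physical picture

Negatively buoyant kelp detritus travels with bottom-layer currents. On a
mid-latitude shelf, the dominant mechanism moving bottom water offshore is
dense shelf water transport (DSWT): differential cooling makes coastal
water denser than offshore water, and the dense water drains offshore
along the seabed as a gravity current. The analysis asks what fraction of
detritus released over kelp habitat crosses the 200 m isobath (the shelf
edge, below the regional mixed layer and surface boundary currents) before
decomposing, and converts that fraction into an areal carbon flux.

## DSWT suitability

Conditions are classified suitable for DSWT when all three hold:

1. **Gradient** — the cross-shore bottom density gradient ∂ρ/∂x < 0
   (x positive offshore; denser water at the coast). The gradient is an
   ordinary-least-squares slope of bottom density against offshore
   distance along each coast-to-edge transect, averaged over alongshore
   rows. OLS was chosen because the criterion only fixes the sign; a
   least-squares slope is the estimator with an exact, testable closed
   form on noisy transects.
2. **Stratification** — the potential energy anomaly
   φ = (1/h)∫₋ₕ⁰(ρ̄−ρ)gz dz, the energy per unit volume needed to fully
   mix the column, must exceed 5 J/m³ when averaged over the analysis
   region (wet cells with depth ≤ 200 m by default). The threshold is
   5 rather than 0 because φ is a regional average: a region is counted
   stratified only when stratification is substantial over it.
3. **Mixing competition** — the gravitational restratifying tendency
   (1/320)·g²h⁴/(ρK_mz)·(∂ρ/∂x)² must exceed the wind destratifying
   tendency δκ_sρ_aW³/h, with κ_s = 0.03(0.63 + 0.066W^{1/3})/1000,
   K_mz = 10⁻² m²/s, δ = 3·10⁻³, ρ_a = 1.2 kg/m³. Both sides are
   evaluated with region means of h, ρ and W, treating the criterion as a
   single regional test. Exception: onshore wind (direction-from within
   225–315°, bounds inclusive since the interval is stated without
   open/closed qualification) reinforces rather than disrupts the
   circulation, so it overrides a failed mixing test.

Tidal mixing is not modelled (the target setting is microtidal) and the
density gradient is treated as thermally driven.

**Numerics of φ.** Density profiles enter as per-cell samples at uniform
fractional heights between bed and surface (10 levels by default). The
profile is treated as piecewise linear, which makes the φ integrand
piecewise quadratic; per-interval Simpson quadrature therefore integrates
it *exactly* at any layer count. This is why the two closed forms that pin
the implementation — two-layer φ = gΔρh/8 and linear-profile
φ = gΔρh/12 — are reproduced to rounding rather than to a discretisation
tolerance (plain trapezoid would be limited to ~10⁻⁴ relative error at
100 layers). φ of a uniform column is zero and φ is invariant to adding a
constant to ρ; both are property-tested.

## Particle tracking

- **Advection**: classical RK4 through velocity that is bilinear in space
  and linear in time between snapshots. Next to land, bilinear weights on
  land nodes are zeroed and the rest renormalised — a constant field stays
  exactly constant up to the waterline and particles are never dragged
  ashore by interpolation. The RK4 global error is verified at 4th order
  (orbit error shrinks ~16× per timestep halving on a solid-body
  rotation).
- **Diffusion**: after the RK4 displacement, an independent Gaussian step
  per axis with standard deviation √(2K_h dt), K_h = 10 m²/s. The printed
  source unit for this diffusivity is dimensionally impossible for a
  diffusivity, so it is implemented as m²/s, the standard unit. The walk's
  ensemble mean-square displacement satisfies the 2-D Einstein relation
  4K_h t, verified to 2% at 10⁵ particles.
- **Timestep**: default dt = 900 s against 3-hourly forcing snapshots —
  stable sub-sampling of a 2 km grid at ≤ 0.3 m/s (CFL ≈ 0.1). The
  shipped full-year analyses use dt = 1800 s with 6-hourly trajectory
  records, which keeps crossing-age resolution (0.25 d) far below the
  9.2 d decay half-life while halving the step count.
- **Threshold velocity** (off by default, sensitivity value 0.045 m/s,
  the conservative flume-derived threshold for small detritus pieces): a
  particle holds position for any step whose local current speed is below
  the threshold. The hold suppresses the random walk too — a particle at
  rest on the seabed does not random-walk — with a toggle to gate
  advection only.
- **Log-profile correction** (off by default): rescales the bottom-layer
  velocity from mid-layer height to a fixed height above the bed by
  ln(z_target/z₀)/ln(z_mid/z₀). Reference height (1 m) and roughness
  length (10⁻³ m) are configuration, as no measured values are built in.
- **Fates**: particles stepping onto land (interpolated depth below
  0.5 m, or no wet neighbour node) freeze at their last wet position and
  are counted beached — there is no refloating, which makes export
  estimates conservative. Particles leaving an open (wet) boundary are
  deactivated and never counted exported unless they crossed the shelf
  edge earlier; exits through a land-backed rim beach instead. Particles
  reaching 1000 m depth (past the deepest export level of interest) are
  deactivated as exported, and their final position is written into the
  next trajectory record so no deep crossing is lost between records.
  Released = active + beached + exported + boundary-exited holds exactly
  at all times.
- No vertical dynamics: no sinking-speed model, no resuspension, no
  wave-driven transport.

## Release scheduling

Counts follow a monthly production step function normalised to daily
weights; the default curve (1.0 in Mar–May, 0.8 Jun–Jul, 0.7 Aug, ~0.3–0.4
otherwise) approximates detrital production that rises in March, peaks
March–May and stays elevated through August. A monthly step (rather than a
smoothed daily curve) keeps the ground truth exact. Daily counts come from
largest-remainder apportionment — deterministic, order-stable, and
budget-exact — and positions are drawn cell-proportional to kelp
probability, uniform within a cell.

## Export accounting

A crossing is the earliest trajectory record whose interpolated seabed
depth reaches the level; no polyline–isobath intersection is computed.
Decomposition is purely a post-processing weight e^(−k·age) at the 200 m
crossing age (k = 0.075 ± 0.031 per day, half-life 9.2 d, measured on the
shelf at 10–50 m depth); deeper-level fractions are reported undecayed
because shelf decay rates need not hold at depth. Monthly export uses the
crossing month (release-month attribution is a toggle), so the twelve
monthly percentages sum exactly to the annual decayed percentage.
Per-pixel contributions normalise by total released mass and are expressed
per-mille, so the raster sum equals 1000 × the annual decayed fraction.
Boundary exits before crossing count as not exported.

## Carbon budget

Areal export = production (2.15 g FW/kelp/day) × kelp density
(6.3 kelp/m²) × FW:DW (0.20) × carbon content of DW (0.30) × 365 days ×
10⁴ m²/ha × exported fraction / 10⁶ g/Mg. A 365-day year reproduces the
0.50–0.86 Mg C/ha/yr range from exported fractions 0.17–0.29 at two
decimals. The estimate is linear in every parameter; no uncertainty is
propagated beyond the exported-fraction range.

## The synthetic scenario: what it emulates, and what it does not

The generator produces the *statistical structure* the analysis needs, in
a local Cartesian frame (x cross-shore positive offshore, y alongshore)
that keeps geographic projections out of unit tests; lon/lat handling
(local equirectangular metric, 1° lat = 111,320 m) lives in the grid
layer for real data.

Defaults, chosen once as representative of a mid-latitude shelf:
100 × 40 km domain on a 2 km grid; depth 0 at the coast, 50 m at 40 km,
200 m (shelf edge) at 60 km, 1200 m at the boundary; cold season May–Sep,
warm Nov–Mar (southern hemisphere), Apr/Oct transitional; cross-shore
bottom density gradient ∓3·10⁻⁶ kg/m⁴ (negative in cold/transition
months, positive in warm); DSWT pulses of 0.15 m/s offshore bottom flow
in 2-day square waves, stratifying the column (surface-to-bed Δρ from
0.02 to 0.5 kg/m³) while they run, with a monthly duty cycle
(0.2 Apr, 0.6 May, 0.65 Jun, 0.5 Jul, 0.35 Aug, 0.1 Sep) emulating
observed cold-season DSWT frequency (~60% of the time in late
autumn/early winter, ~20% in April); pulses decay exponentially
(20 km e-folding) past the shelf edge so exported material continues
down-slope; alongshore current 0.05 m/s; warm-season onshore bottom flow
0.02 m/s; cross-shore flow tapers to zero where depth < 10 m (no flow
through the coast); warm-season southerly seabreezes (3–12 m/s diurnal),
cold-season westerly (onshore) storms of 15 m/s every 7 days over a 5 m/s
background; kelp probability 1 − depth/50 m, zero on land and beyond
50 m. Pulses are square waves because they give unambiguous ground truth
for export accounting; a ramp is configurable. The alongshore axis is
treated as periodic by the default pipeline (the scenario is an idealised
channel), so alongshore advection does not artificially drain the domain.

By construction, the classifier's suitable timesteps coincide exactly with
pulse windows (cold/transition gradient is negative, the column is
stratified only during pulses, and storms are onshore), and export can
only occur during those windows. Passing the end-to-end checks therefore
shows that the chain — classifier, scheduler, tracker, accounting — is
internally consistent and conserving; it does **not** show that any real
shelf exports a particular fraction. The synthetic fields lack mesoscale
eddies, boundary currents, tides, reef-scale retention, realistic wind
variability and curvilinear geometry, and the headline fractions obtained
on them (≈62% undecayed, ≈32% decayed with the default seed) are
properties of the scenario, not predictions. Results that require
realistic reanalysis forcing and a measured kelp distribution — annual
export percentages, the observed 0.92 export–suitability correlation,
absolute monthly suitability — are echoed here only as qualitative
expectations: export concentrates in the cold season, decayed export is
well below undecayed, and monthly export correlates strongly (r > 0.8)
with monthly suitability.

## Problem sizes of the shipped analyses

The full-year acceptance run uses the default 2 km grid, 3-hourly
forcing, dt = 1800 s, 6-hourly records and 10⁴ particles (about a minute
of compute); the orchestration tests use a 4 km grid with 12-hourly
forcing and a few hundred particles. Both sizes were chosen so the
statistics they report (export fractions, monthly correlation) are stable
to well within the tolerances asserted on them.

## Known limitations

- Beached mass is permanently lost; with storm resuspension the cold
  season would re-mobilise some of it, so synthetic export fractions are
  conservative in that respect.
- Crossing ages are quantised at the record interval; decay weights
  inherit that (≤ 0.25 d, i.e. ≤ 2% of mass at the default half-life).
- The classifier averages Eq.-(3) inputs over the region rather than
  evaluating it per cell; spatial extent and transect placement are
  configurable because no canonical definition exists.
- Only rectilinear grids (Cartesian or lon/lat) are supported; forcing on
  a curvilinear grid must be regridded to a rectilinear one before
  loading.
- Salinity-driven density gradients, tides, dissolved organic carbon,
  burial and sequestration timescales are out of scope.
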