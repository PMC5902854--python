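# Methods

## Model and assumptions

The simulator solves a two-compartment population model on a rectangular
urban domain. The winged compartment `M` (mature female mosquitoes) is
advected by wind and disperses diffusively; the aquatic compartment `A`
(eggs, larvae, pupae pooled) is immobile. The compartments couple through
maturation (`γA(1 − M/k₁)` feeds `M`) and oviposition (`rM(1 − A/k₂)`
feeds `A`); both lose individuals to natural mortality (`μ₁, μ₂`) and,
under control scenarios, to insecticide killing terms (`h₁` adulticide,
`h₂` larvicide). The area-support coefficient `ψ(x,y) ∈ (0,1]` scales how
much population a location sustains: the observable quantities are the
totals `ψM` and `ψA`, and `ψ` multiplies the time derivative, so sparse
locations (streets, `ψ = 0.3`) respond faster per unit density than dense
ones (blocks, `ψ = 1`).

Assumptions worth keeping in mind:

* coefficients are piecewise constant per land-use region and constant in
  time (except the wind, which may follow a day/night schedule);
* the logistic factors are applied exactly as written — a transient
  overshoot of `A` above `k₂` flips the oviposition term negative and is
  not floored;
* `k₁ = 25` and `k₂ = 100` function as dimensionless density scales even
  though the source tables nominally attach day⁻¹ units to them;
* the aquatic phase has no transport terms of any kind.

With killing terms off, the spatially homogeneous reactions admit the
extinction state and a coexistence equilibrium `(M*, A*) ≈ (23.776,
97.140)` for the base rate table (`γ = 0.2`, `r = 30`, `μ₁ = 0.04`,
`μ₂ = 0.01` day⁻¹); the package solves it by reducing to a scalar root
(Brent, relative tolerance 1e-12) and the test suite cross-checks it
against an independent 2-D root find and as a fixed point of the full
discrete solver (per-step drift < 1e-8).

## Units: the transport-coefficient question

The per-region transport tables carry values such as `D = 1.25×10⁻²` and
`v = 5×10⁻²` with nominal units m²/s and m/s, while every rate constant
is per day. These numeric values descend from the classic traveling-wave
literature on *Ae. aegypti* dispersal, where the same numbers carry
km²/day and km/day. The discrepancy is consequential: read as m/s, street
wind (0.1 m/s ≈ 8.6 km/day) crosses a 500 m neighborhood in under two
hours and the whole domain saturates within days, flattening any
strategy comparison; read as km/day, invasion takes weeks — the time
scale the scenario narratives describe. The presets therefore interpret
transport values in km/day by default. The interpretation is explicit and
configurable (`transport_unit`: `m/s`, `m/day`, `km/day`): all three
readings go through the same conversion layer into the internal unit
system (meters and days), and the stability-bound unit test exercises the
m/s reading against a hand-computed value (2.667 s for a street cell on a
2 m grid).

## Discretization

Cell-centered uniform mesh; fields are `(ny, nx)` arrays with row 0 at
`y = 0`. Region labels are assigned by cell-center sampling of a painted
rectangle list (last rectangle wins), matching the piecewise-constant
coefficient model: no area-weighted mixing at region boundaries.

Transport of `M` uses face fluxes `F = −v_f M_up + D_f ΔM/Δh` with

* `v_f`: arithmetic mean of the adjacent cell velocities; the upwind value
  `M_up` is the upstream cell (arithmetic mean as a tie-break at `v_f = 0`,
  where the advective flux vanishes anyway);
* `D_f`: harmonic mean of the adjacent cell diffusivities (preserves flux
  continuity across block/street discontinuities; an arithmetic-mean
  option exists);
* zero-gradient sides: no diffusive flux, advective outflow uses the
  boundary-cell value, inflow is zero (zero-net-influx reading of an
  isolated neighborhood);
* fixed-value sides: a ghost value one spacing outside the face enters
  both the upwind and the diffusive flux.

For piecewise-constant coefficients this operator is affine in `M`, so it
is assembled once per wind window as a sparse matrix plus a Dirichlet
offset vector; a step then costs one sparse mat-vec plus a few vector
operations. Time integration is forward Euler:

```
M ← M + (Δt/ψ)(div F + R_M),   A ← A + (Δt/ψ) R_A
```

with the step size from the combined explicit bound
`Δt ≤ safety · min ψ / (|vx|/Δx + |vy|/Δy + 2Dx/Δx² + 2Dy/Δy²)`
(safety 0.9 by default; `ψ` enters because the update divides by it).
The bound is re-evaluated at every wind-schedule switch. When no
transport is active anywhere the bound is infinite and a configurable cap
(600 s default) applies; the verification fixtures lift the cap so the
convergence studies see `Δt ∝ Δx` (advection) and `Δt ∝ Δx²` (diffusion).

Degenerate inputs and tie-breaks: `ψ = 0` is rejected (minimum 1e-6)
because the update divides by `ψ`; a face between two zero-diffusivity
cells carries no diffusive flux; densities below −1e-10 (or NaN) abort
the run with the failing time, while smaller round-off undershoots are
clipped to zero. Positivity — not boundedness — is the enforced
invariant: transient overshoot above `k₁`/`k₂` is legitimate model
behavior.

Verified numerical properties (test suite): discrete conservation of
`∫ψM dΩ` to 1e-10 relative over 1000 transport-only steps; positivity
under the stability bound across randomized parameter draws; elementwise
agreement (1e-12) with an independently coded scalar upwind/diffusion
reference on single-row problems; first-order self-convergence on smooth
advected profiles (a discontinuous top-hat degrades to the expected
fractional rate ≈ 0.5–0.7); second-order convergence to the analytic heat
kernel on pure diffusion.

## Scenario reconstructions

The published study areas are available only as figures, so the presets
encode approximate reconstructions — label counts, proportions and
adjacency are faithful; coordinates are not surveyed.

* `example1`: 200×200 m, nine 40 m blocks on a 20 m street lattice.
  The seed location is not documented; the preset seeds the central
  block.
* `example2`/`example3`: 500×500 m; a 4×5 lattice of 100×76 m slots on
  20 m streets, with the park in a central slot and two slots left open
  (street-level squares), giving exactly 17 building blocks, one park and
  three labels. Both phases are seeded in the park.
* `example3` variants: `all_streets` sets `h₁ = 0.928`/day on every
  street cell; `one_street` sets `h₁ = 7.6`/day on the central vertical
  street plus a surrounding margin (corridor x ∈ [225, 275] m intersected
  with street cells, ≈ 13,400 m²). The corridor width was chosen so that
  `h₁ × treated area` is the same in both variants to within a few
  percent — the "same total amount of insecticide" constraint. `h₂ = 0`
  everywhere: space-sprayed adulticides do not reach the aquatic stages.
* `example4`: 400×400 m; 3×4 blocks, 20 m streets, a 50 m beach strip on
  the sea-facing (right) side carrying a zero-Dirichlet condition for
  `M`. The wind alternates on a 12 h/12 h cycle (day 06:00–18:00,
  configurable): onshore-oblique by day, alongshore-reversed by night,
  with beach values twice the street values componentwise. The "small
  park" seed is a 40 m interior square.

Seed amplitudes are not documented either; presets use `M₀ = k₁ = 25`
and `A₀ = k₂ = 100` inside the seed region. The headline reduction
percentages are insensitive to this choice (tested: quartering the
amplitudes moves the all-streets winged reduction by < 0.01 points),
because reductions are scale-free ratios and the populations approach
local equilibria well before day 42.

Insecticide application is constant over the whole run; evaluation of
reduction percentages defaults to day 42 (the end of the six-week
window) and is configurable.

## Problem sizes and tiers

The production tier for the city-center comparison is 125×125 cells
(Δx = 4 m), the choice made in `scripts/acceptance.py`; the test suite
uses a 50×50 coarse tier (Δx = 10 m). The reduction percentages are
grid-converged across Δx = 10/5/4 m to well under one percentage point
(all-streets winged: 27.52/27.52/27.49%), so the coarse tier is adequate
for assertions. Default preset resolution for interactive use is
Δx = 2 m.

## What the comparison does and does not show

With the base rate table, local net reproduction is fast (dominant
linearized growth rate ≈ 2.33/day), so any seeded region saturates
within about ten days and day-42 totals sit near a (boundary-leaky)
steady state. A street under `h₁ = 0.928`/day remains strongly
super-critical — `γr = 6` far exceeds `(μ₁+h₁)(μ₂+γ) ≈ 0.20`, and
confinement would require `h₁ ≳ 28`/day — so spraying thins the street
standing population (street-cell equilibrium density drops from ≈ 23.8
to ≈ 10.9) but cannot stop the invasion of the blocks. Consequently the
simulated aquatic reductions are small (≈ 1%): wherever the winged
density stays above roughly one mosquito per unit area, oviposition keeps
the breeders saturated. The qualitative ranking — the same amount of
insecticide spread uniformly over all streets beats concentrating it on
one corridor, for both phases — is robust across resolutions, seed
amplitudes and unit readings.

## Known limitations

No temperature/precipitation dependence of the rates; no stochastic
demography; rectangle-only geometry (no GIS import); first-order upwind
transport (numerical diffusion sharpens with resolution but is present);
explicit time stepping only. The synthetic layouts omit features of real
neighborhoods (irregular block shapes, vegetation heterogeneity, indoor
breeding-site structure), so passing tests demonstrate correctness of
the numerics and internal consistency of the scenario comparison, not
calibrated predictions for the real cities.
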