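# aedes2d

Finite-volume simulation of urban *Aedes aegypti* population dynamics:
coupled winged (mobile) and aquatic (static) subpopulations on a
heterogeneous city raster with wind advection, diffusion, logistic phase
coupling, and insecticide killing terms.

## Who this is for

Vector-control modelers and public-health analysts who want to compare
mosquito-suppression strategies (e.g. where to spray adulticide) on a
realistic block/street layout before committing resources, and numerical
analysts who want a small, fully verified reaction–advection–diffusion
testbed with first-order upwind transport.

## Model

The winged-female density `M(x, y, t)` and the aquatic density
`A(x, y, t)` (eggs + larvae + pupae) obey

```
∂(ψM)/∂t = −∇·(vM) + ∇·(D∇M) + γA(1 − M/k₁) − (μ₁ + h₁)M
∂(ψA)/∂t =                      rM(1 − A/k₂) − (μ₂ + h₂ + γ)A
```

where `ψ(x,y) ∈ (0,1]` is the *area-support coefficient* (the population a
location can sustain; the observable total is `ψM`), `v` the wind, `D` the
diffusivity of random flight, `γ` the aquatic→winged maturation rate, `r`
the oviposition rate, `k₁, k₂` logistic capacity scales, `μᵢ` mortalities
and `hᵢ` insecticide killing rates. Only the winged phase is transported.
All coefficients are piecewise constant over land-use regions (building
block, street, park, beach), set from per-region tables.

The solver is a cell-centered finite-volume scheme: first-order upwind
advective fluxes, two-point central diffusive fluxes (harmonic-mean face
diffusivity), forward-Euler time stepping under a combined
advective–diffusive CFL bound scaled by `ψ`. Boundaries are zero-gradient
(isolated neighborhood, outflow permitted) or fixed-value (zero population
on a sea-facing side). Four scenario presets reconstruct the study areas:
a generic 200 m quarter (`example1`), a 500 m city-center layout with 17
blocks and a park (`example2`), the same layout with adulticide along one
street corridor or along all streets (`example3:one_street`,
`example3:all_streets`), and a 400 m beach-front layout with a day/night
sea-breeze cycle (`example4`).

## Worked example

Compare spraying every street (`h₁ = 0.928/day`) against the untreated
baseline on a 50×50 grid:

```
$ aedes2d --log-level warning compare --preset example3:all_streets \
      --baseline example2 --dx 10 --out compare.csv
winged: 27.52% reduction at day 42
aquatic: 1.36% reduction at day 42
```

Both scenarios seed the park with both phases, run six weeks, and
integrate the totals `∫ψM dΩ` and `∫ψA dΩ`; the printed percentages are
`100·(1 − treated/baseline)` at day 42. The winged phase drops by ~27%
(the adulticide thins the street population standing between park and
blocks), while the aquatic phase — which the adulticide does not touch
directly — barely responds, because by week six every seeded region sits
near its local equilibrium where oviposition saturates the breeders.

A full run with snapshot fields:

```
$ aedes2d run --preset example1 --dx 10 --days 42 --out ex1_out
```

writes `totals.csv` (time series of both domain totals), `psiM_day{0,21,42}.csv`
and `psiA_day*.csv` (gridded total-population snapshots), the region
raster, a JSON run manifest and a solver health report (CFL, positivity,
discrete mass balance of a transport-only twin).

Library use mirrors the CLI:

```python
import aedes2d as a
result = a.simulate(a.get_preset("example2", dx=10.0))
print(result.totals.tail(1))          # day-42 totals
```

## Limitations

Block layouts are approximate reconstructions of the published maps
(counts, proportions and adjacency — not surveyed coordinates). Transport
coefficient tables are interpreted in km/day (see `docs/methods.md` for
the unit discussion). No temperature or rainfall dependence of the rates,
no stochastic demography, and no coupling to human disease dynamics.
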