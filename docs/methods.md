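# Methods

## The model

A system is an energy-level diagram: species `j` with level energy `G_j`,
integer composition `c_j` (elemental constituents per entity) and
population `N_j`, connected by transformations that convert stoichiometric
multisets of species into one another while exchanging a quantum of energy
`deltaQ` with the surroundings.  Quanta carry energy only, so every
transformation must balance composition exactly; this is validated
structurally.  All energies are measured in units of the thermal energy
`kT` with Boltzmann's constant set to 1.

State functions:

- chemical potential `mu_j = G_j + kT ln N_j`;
- affinity of transformation `r`: `A_r = -dmu_r + deltaQ_r` with
  `dmu_r` the stoichiometry-weighted products-minus-substrates potential
  difference.  Positive affinity drives net forward flux; all affinities
  zero defines thermodynamic balance;
- entropy, in three evaluations (see below).

Dynamics follow the least-time free-energy-consumption rate law: each
transformation carries an event rate linear in its affinity,

    v_r = sigma_r A_r / kT,    dN_j/dt = sum_r S_jr v_r,

with `sigma_r >= 0` the conductance of the mechanism and `S` the net
stoichiometric matrix.  The dissipated power is

    T dS/dt = sum_r v_r A_r = sum_r sigma_r A_r^2 / kT >= 0,

which vanishes exactly at balance.  The rate law is deliberately linear in
the affinity — no mass-action exponential variants — because the flux is
conceived as proportional to the free energy it consumes.

## Entropy evaluations

`system_entropy` offers three modes.

- `affinity`: `S = sum_j N_j + (1/kT) sum_r A_r W_r`, with `W_r` the
  product-side population of transformation `r`.  At balance this reduces
  exactly to `S = sum_j N_j`, the count of entities.
- `stirling`: the per-population log-probability form
  `S = sum_j [N_j ln P1_j - (N_j ln N_j - N_j)]`, where `ln P1_j`
  collects substrate log-populations and per-event energy drops over the
  transformations producing `j` (a species with no producer contributes its
  own `ln N_j`).  For diagrams in which each species has at most one
  producing transformation — every built-in chain — `stirling` and
  `affinity` coincide algebraically.
- `exact`: as `stirling` but with the exact `ln N_j!` (log-gamma).  The
  stirling-vs-exact gap is the true Stirling error; it is below 5% once all
  populations reach ~100 and shrinks monotonically as populations scale up.

Along a trajectory, `entropy_series` is **not** the state-function
approximation re-evaluated per sample: that approximation's time derivative
contains sign-indefinite `dA/dt` terms and is not exactly monotone.
Instead the equation of change is integrated literally — the series is the
initial affinity-mode value plus the cumulative trapezoid of `power/T`.
Since power is a sum of squares, the series is non-decreasing by
construction; this is the package's reading of entropy production as
free-energy consumption.

## Numerical integration

Integration runs in reaction-extent space, `N(t) = N0 + S xi(t)`.  Because
the columns of `S` are elementally balanced integers, total matter
`sum_j c_j N_j` in a closed system is conserved to float rounding
(~1e-15 relative) independent of integrator error.  The default solver is
LSODA with `rtol 1e-8`, `atol 1e-10` (artifact choices), sampled at
user-set times.

Near extinction, populations entering logarithms are clipped at a hard
floor (1e-12).  The divergent potential of a nearly extinct species gives
its producing channels a strongly positive affinity, so the flux itself
pushes populations back above the floor; the floor is an inert guard in
well-posed systems.  Populations are additionally clipped at zero when
stored.

`euler_evolve` is a deliberately naive fixed-step explicit Euler reference
that steps populations directly (not extents).  It serves as a brute-force
cross-check of the adaptive path.  The equivalence comparison is run from a
strictly positive initial state (small polymer seeds, `polymer_seed`
option): from an exactly extinct start the first-order method must cross
the potential-floor kink, where its error constant is inflated for reasons
that say nothing about either integrator's handling of the smooth problem.

Steady-state detection requires BOTH the power and every |affinity| at or
below a tolerance (default 1e-6): power alone can vanish while a
zero-conductance channel still holds free energy.

## Scenarios

- `two_level`: A <-> B with one quantum-coupled channel; closed-form
  balance ratio `N_B/N_A = exp((G_A - G_B + deltaQ)/kT)`, including the
  compensation case `deltaQ = G_B - G_A` where the ratio is exactly 1.
- `chain`: the assembly cascade `X_j + X_1 -> X_(j+1)`, `c_j = j`.  The
  per-step quantum coupling makes each step downhill by a stated margin
  (default +1 kT standard affinity at unit populations) so that relaxation
  shows a clear approach to a structured balance.  The closed default puts
  all matter in monomers; it is the workhorse for conservation, entropy
  and factor-linearity checks.
- `chain` with `source=True`: a reservoir species (composition 1) feeds
  monomers through a slow, elementally balanced transformation
  (conductance ratio 50 between assembly and feed; reservoir 1000 units,
  monomer seed 0.01).  The whole cascade then *grows* as the reservoir
  drains: with assembly much faster than the feed, the chain stays
  quasi-equilibrated against the instantaneous monomer population and
  `N_j` tracks `N_1^c_j`.  This co-growth is the regime in which the
  sigmoid cumulative curve, the power-law body (`ln N_j` vs `ln N_1` slope
  `c_j`) and the approximately constant free-energy factor `alpha_j`
  appear.  A closed all-monomer chain cannot show that regime: there the
  monomer *depletes* while polymers grow, so the log-log slope is negative
  — the power-law pattern belongs to systems growing by influx of
  elemental constituents.  The conductance ratio is a timescale-separation
  choice (quasi-static tracking needs assembly relaxation fast against the
  feed), not a fitted number.
- `driven`: the chain plus a sinusoidal modulation of one transformation's
  quantum coupling, amplitude in kT.  The drive lives in a separate
  schedule object, so zero amplitude reproduces the undriven system
  bit-for-bit.  Small amplitudes entrain the populations to the drive
  period (checked by periodogram); amplitudes of several kT keep the
  system permanently off balance.  Driven behavior is characterized by
  loss of stationarity and entrainment diagnostics only — no
  Lyapunov-exponent claims.
- `make_random_system`: seeded random valid diagrams (compositions from
  {1,1,2,3}, elementally balanced isomerizations and assemblies) for
  property sweeps.

## Pattern analysis

Regime segmentation works on the logarithm of the central-difference
growth rate `g = dN_j/dt`: both a pure exponential and an exponential
saturation make `ln g` *exactly* linear in time, so phase edges appear as
predictive-residual breaks (a candidate point is rejected when its residual
against the current window's fit exceeds 5% of the window's spread).  On
exactly piecewise data this localizes boundaries to one sampling interval.
Samples where |g| falls below 1e-6 of its peak (converged tail, pre-growth
plateau) are excluded, as is anything outside the contiguous active stretch
containing the growth peak; a series whose active stretch has more than
20% negative growth samples (e.g. under periodic driving) is flagged
segmentation-undefined rather than segmented.

Reported fits: onset — `ln N_j` vs `t` (empirical exponential rate), with
the window greedily trimmed until R^2 meets the goodness threshold
(default 0.98, minimum 5 samples); body — `ln N_j` vs `ln N_1`
(power-law exponent); flattening — `ln g` vs `t` (approach rate).  The
onset rate is reported as fitted; whether it matches the sum of
conductances depends on how strongly the onset approximation holds, so the
comparison is left to the caller rather than asserted.

The lognormal signature is tested at the level the theory states it:
linearity of `ln phi_j` (`phi_j = N_j exp(G_j/kT)`) in the composition
`c_j`, over populated species, with verdict threshold R^2 >= 0.95.  It is
not a distributional hypothesis test on samples.

`alpha_factor` computes `alpha_j = exp(sum A_r / kT)` over a BFS path of
transformations from the elemental species (smallest composition, earliest
in the species list on ties) to the target; it is exactly 1 at balance and
its relative drift over the body window measures how well the diagram
keeps its form.

The entropy-vs-potential curve aggregates the potential axis as the
population-weighted mean potential (the abscissa's aggregation is an
artifact choice), excludes non-positive values with a count, and fits the
log-log slope over the central 10–90% quantile range; both axes are in kT
units.

## What the generators do and do not emulate

The scenarios produce smooth deterministic population dynamics in the
continuum statistical limit.  They emulate the energetic structure of
growing and relaxing systems (level spacing, quantum coupling, conductance
hierarchies) but not demographic noise, discrete small-number events
(no Gillespie-type simulation — abrupt small-system changes are outside
scope), spatial structure, or mechanism evolution beyond an optional
user-supplied conductance rule.  Passing tests therefore demonstrate the
internal consistency of the formalism and the emergence of its predicted
patterns under the stated conditions, not claims about any empirical
neural or social dataset.

## Degenerate inputs and tie-breaks

- Extinct species: chemical potential undefined (raised); entropy
  contributions take the `0 ln 0 = 0` limit; `entity_log_probability`
  returns `-inf` when a vital substrate is missing.
- `stationary_ratio` covers 1:1 unit-coefficient transformations only;
  general fixed points are found numerically.
- `power_law_slope` raises on a constant regressor; factor fits need at
  least 3 populated species; `alpha_factor` raises when no transformation
  path reaches the target.
- Trajectory CSVs are written with shortest-round-trip floats and re-read
  with round-trip parsing, so export/import is bit-exact.

## Problem sizes

The shipped checks run at desk scale: 100 random systems of up to 5
species over 60 samples; chains of 3–6 levels; a 10^6-step Euler reference
on the 3-level chain over t in [0, 10]; growth trajectories of ~3000
geometrically spaced samples.  These sizes were chosen so the full suite
exercises every guarantee in well under a minute of integration time while
leaving the asymptotic regimes (populations ~10^2–10^3) clearly visible.

## Known limitations

- The affinity-mode entropy is a near-balance approximation; far from
  balance it can exceed the exact log-probability value substantially (and
  the two differ structurally for species with several producing
  transformations).
- The linear flux law has no saturation: enormous affinities (deeply
  extinct substrates) produce fluxes bounded only by the logarithmic
  potential floor.
- Regime segmentation assumes an essentially monotone cumulative curve;
  oscillatory trajectories are flagged, not segmented.
- The quasi-equilibrium co-growth regime requires a conductance hierarchy;
  with comparable feed and assembly conductances the body window shrinks
  and the power-law exponent is biased by tracking lag.
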