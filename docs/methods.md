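# Methods

## Model

Each simulated area is a lattice of 100 cm² cells; a cell holds one
individual or is empty. A run comprises `n_areas` non-interacting replicate
areas sharing one metacommunity (there is no inter-area dispersal). The
lattice shape for a target area A m² is the most-square W × H grid with
W·H ≥ round(100·A) cells and excess < W; realized dimensions are recorded in
experiment manifests.

A time step (one year) is two synchronous phases:

1. **Mortality.** Every occupied cell is emptied independently with
   probability `mortality`. There is no density dependence; fire mortality
   is folded into this rate, which is why the model carries no explicit fire
   events — the rates were defined for a high-frequency prescribed-burn
   regime, and the neutrality assumption is only claimed for that regime.
2. **Recruitment.** Every cell empty after phase 1 draws a birth with
   probability `birth`. A successful birth is an immigration event with
   probability `immigration` (independent Bernoulli per birth), in which
   case the recruit's species is drawn from the metacommunity relative
   frequencies. Otherwise the recruit comes from the local pool, evaluated
   against the *post-mortality* configuration: recruits of the current step
   never parent within it.

Local recruitment differs between the two model variants:

- **Non-spatial:** the recruit's species is sampled from the realized
  relative frequencies of the area's survivors — implemented as copying a
  uniformly random survivor, which is the same distribution at O(1) cost.
  If the area has no survivors and immigration was not drawn, the cell
  stays empty. A `local_pool="initial"` switch instead samples the area's
  initial composition, covering the other reading of "the frequency
  distributions for each simulated area".
- **Spatial:** a parent is chosen among occupied cells within Chebyshev
  radius `max_dispersal_cells` (default 5, i.e. an 11 × 11 window; maximum
  center-to-center reach √2 · 0.5 m ≈ 0.71 m) with probability proportional
  to exp(−d / `kernel_scale_cells`), where d is the Euclidean
  center-to-center distance in cell units under periodic boundaries. An
  empty window leaves the cell vacant: immigration is the only
  metacommunity channel. The kernel scale is not an empirically estimated
  quantity; the default of 1 cell makes dispersal strongly local while the
  large-scale limit recovers uniform parent choice (used as an internal
  consistency check against the non-spatial rule).

On lattices smaller than the dispersal window, distinct offsets can wrap
onto the same torus cell; the window keeps each wrapped target once, at its
minimal image distance, so no parent is double-weighted.

Boundaries are periodic in the spatial model (eliminating edge effects on
neighborhood recruitment) and irrelevant in the non-spatial model, whose
lattices are marked bounded.

**Initialization.** Every cell of every area is filled by an i.i.d. draw
from the metacommunity frequencies. Full initial occupancy is the default
(`initial_occupancy` exposes a fraction for sensitivity checks): the source
description populates cells "randomly from the distribution" without an
occupancy fraction, and full occupancy is the simplest reading.

**Output.** Richness per step is the pooled count of distinct species over
all areas (a run is one observation for the sensitivity analysis; per-area
richness can be tracked with `track_per_area`). Normalized richness is the
ratio S(end)/S(1), richness at the final step over richness at step 1
(after the first update); a `relative_change` switch yields
(S(end) − S(1))/S(1) instead. A community extinct by step 1 reports 0
rather than 0/0, keeping sensitivity-analysis output vectors finite.

**Randomness.** A run's master seed spawns one `numpy` SeedSequence child
per time step (child 0 initializes). Within a step, draws follow a fixed
order (mortality over occupied cells in C order; then per empty cell birth,
immigration, species). Identical seed, parameters and metacommunity give
bit-identical trajectories, and runs of different lengths share their common
prefix of draws. Per-area sub-streams were deliberately not used: recruitment
is vectorized across areas, so all areas of a step share one stream; changing
`n_areas` therefore reshuffles a step's draws, which no supported analysis
relies on.

## Census processing

Mapped censuses arrive as `plot,year,x_cm,y_cm,species` tables at 10-cm
resolution, at most one individual per cell per year. A metacommunity at
grain g ∈ {10, 20, 50, 100, 200} cm counts, per species, the number of
g × g blocks (anchored at each plot's origin; edge blocks may be partial)
containing at least one individual of that species. Presence–absence
coarsening preserves richness exactly and per-species counts are
non-increasing in grain — both are tested properties. Multiple species may
be counted in the same block, so coarse totals are block–species incidences,
not an occupancy partition.

Demographic rates come from consecutive surveys of the same plot:
mortality = (occupied cells whose original species is absent from that cell
at the next survey) / (occupied cells); birth = (cells empty then occupied)
/ (cells empty). A cell whose occupant changed species scores one death and
is logged as a replacement; it does not enter the birth numerator, matching
the cell-wise definitions literally. Zero denominators raise
`UndefinedRateError` — a rate with no at-risk cells is undefined, not zero.
Averaging over plot-year pairs is an unweighted mean of per-pair rates
(pairs with an undefined rate are dropped from that rate's mean); the
alternative pooled-transition estimator was not used because the source
procedure averages "across plots, years, and habitats", which reads as a
mean of rates.

## FAST sensitivity analysis

Five parameters are varied: birth (0.2–0.6), mortality (0.2–0.6),
immigration (0.01–0.25), area (1–25 m²), number of areas (1–30). The design
follows the extended FAST scheme: for each parameter block, N points
(default 100 per parameter, hence 500 rows) are placed along the search
curve

x_j(s) = low_j + (high_j − low_j) · (1/2 + arcsin(sin(ω_j s + φ_j))/π)

over N equispaced s ∈ (−π, π), with the parameter of interest carrying the
high frequency ω_max = ⌊(N−1)/2M⌋ and the others complementary frequencies
in 1..⌊ω_max/2M⌋. Phases φ_j default to 0 for exact reproducibility (a
design-seed option would randomize them; the default design is fully
deterministic). The interference factor is M = 4, the standard choice;
N > 4M² is enforced so read harmonics stay below Nyquist and clear of
complementary harmonics (checked structurally in the tests).

The first-order index of parameter i is the output block's spectral power
at harmonics 1..M of ω_max divided by its total spectral power up to
Nyquist. The estimator is validated against the Ishigami function's
closed-form variance decomposition (within 0.02 at N = 1000) and sums to ≈1
on additive models. Because the simulator's output is stochastic, residual
Monte-Carlo variance spreads over all frequency bins and the read harmonics
carry a noise floor of roughly M/((N−1)/2) of the noise share; indices below
~0.05 should be read as "indistinguishable from zero" at the default design
size.

Integer-valued factors (number of areas; lattice dims from area) are kept
continuous in the design and discretized only at simulator evaluation, so
the Fourier structure of the design is exact and discretization noise is
absorbed into the residual. Replicates share the design matrix and differ
only in simulator seeds; per-row seeds derive from the replicate seed via
`SeedSequence.generate_state`. Results are reported per replicate, not
pre-averaged. The full scenario grid is models × habitats × grains
(2 × 2 × 5 = 20 at study scale).

## Synthetic data

The generator emulates a field campaign: 30 plots of 1 m × 3 m on a 10-cm
grid, four yearly surveys, ~123 species, > 7,000 recorded individuals with a
strongly right-skewed abundance distribution. Species abundances are drawn
from a log-series (shape from Fisher's α via x = T/(T+α); default α = 20,
chosen once as realistic for a community of this richness-to-abundance
ratio), given a guaranteed minimum of one individual per species and
largest-remainder rounding to an exact total. Surveys after the first apply
per-cell death and colonization at known probabilities (defaults 0.4 and
0.3, inside the empirical 0.2–0.6 rate band), so the series is exact ground
truth for the rate estimator — recovery within 3 binomial standard errors is
the module's core tested property, at 10³–10⁵ transitions.

What the generator does *not* emulate: spatial aggregation of clonal
plants (cells are independent, so censuses carry no spatial
autocorrelation), per-habitat differences in distribution shape, detection
error, or species identities. Tests passing on synthetic data therefore
validate the estimators' cell-wise logic and the simulator's dynamics, not
robustness to clumped or imperfect field data.

## Problem sizes and numerical choices

- The packaged sensitivity-ordering check runs the non-spatial model over
  the full 500-row design with 3 replicates, areas capped at 9 m² — a
  scaled-down configuration that finishes in about 90 s on one CPU while
  preserving the qualitative ordering (birth and mortality < 5% of output
  variance; immigration the dominant neutral parameter). Full-scale areas
  (≤ 25 m²) run through the same code path.
- The spatial ≈ non-spatial equivalence check uses an 11 × 11 torus (1.21
  m²), which the dispersal window covers exactly, with kernel scale 10⁹ so
  parent choice is uniform over survivors; 200 replicates per variant,
  compared within 3 Monte-Carlo standard errors.
- Metacommunity cumulative frequencies are clamped to end at exactly 1.0
  before `searchsorted` sampling, guarding against rounding at the last bin.
- `area_to_dims` errors below one cell (area < 0.005 m²); degenerate kernel
  or probability inputs are rejected at `SimulationParams` construction.

## Known limitations

- No explicit fire events, burn severity, species traits, density
  dependence, or speciation; neutrality is assumed, not tested, by the
  simulator itself.
- The non-spatial model's "local pool" ambiguity (realized vs initial
  composition) is resolved by a switch, but only the realized default is
  exercised by the sensitivity experiment.
- First-order indices only; interaction (higher-order) effects are out of
  scope.
- With immigration = 0 and finite areas, communities drift monotonically
  toward extinction of diversity; normalized richness then reflects decay
  speed, not a stationary state.
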