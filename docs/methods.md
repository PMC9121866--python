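# Methods

## Model structure

The simulator is an individual-based model on a regular 250 m grid. State is
carried by three coupled structures: a static prey-production field
(kg/month per cell), a road-class raster (none / secondary / primary, with a
proposed railway treated as primary), and a population of tiger agents.
Breeding females own exclusive, rook-connected cell sets (territories);
breeding males own sets of up to six females. Time advances in months; every
month executes a fixed event order: (1) aging, (2) survival draws including
starvation and orphan deaths, (3) release of dead owners' cells, (4) female
settlement and territory expansion with border contests, (5) male range
assembly, dispersal jumps, challenges and infanticide, (6) conception,
gestation and births, (7) recording. Deaths precede settlement so vacancies
created by road mortality can be recolonized within the month — the
compensatory-immigration pathway the occupancy results depend on.

All stochasticity flows through a single PCG64 stream per replicate,
consumed in scheduler order, which makes a run a pure function of
(configuration, seed). Replicate r uses seed base_seed + r. Experiment arms
that share a replicate seed also share the burn-in trajectory bit-exactly;
the engine exploits this by branching a deep-copied state at activation,
which is observationally identical to running each arm end-to-end.

## Parameters

Vital rates and behavioral constants default to the Chitwan field estimates
and are bundled in one `Params` dataclass (all rates annual unless noted):

* survival — breeding male 0.8, breeding female 0.9, dispersing/transient
  male 0.65, transient female 0.7, juvenile 0.9, cub 0.6;
* fecundity — 0.9 for three-year-old resident females, 1.0 at four plus;
  gestation 3 or 4 months with equal probability; litter size pmf
  (1..5) = (0, 0.23, 0.58, 0.17, 0.02); 50:50 birth sex ratio;
* territory — utilized fraction 0.1 of summed cell production, minimum
  76 kg/month (2.5 kg/day × 365 / 12), maximum 167.3 kg/month
  (5.5 kg/day × 365 / 12), at most 48 cells (3 km²) annexed per month,
  patch-takeover probability 0.25, settlement exclusion radius 2 km ideal /
  1 km relaxed, female dispersal cap 33 km from the natal center;
* males — 3 km search radius, at most six females, 66 km dispersal cap,
  challenge deaths 0.25 (challenger) / 0.6 (incumbent), infanticide 0.79
  (cub) / 0.24 (juvenile);
* road effects — annual survival 0.297 with a primary road/railway cell in
  the territory, 0.81 with only secondary cells; prey depleted linearly to
  zero at infrastructure, recovering at 5 km (primary/railway) and 2 km
  (secondary).

Annual-to-monthly conversion uses the 12th root for survival (preserving the
compounded annual rate exactly) and the complementary hazard
1 − (1 − p)^(1/12) for breeding probabilities, so p = 1 makes conception
certain in the first eligible month.

## Design choices where the rules were open

* **Expansion stopping rule.** A female expands only while her utilized prey
  is below the 76 kg/month minimum and never past the 167.3 maximum. This
  yields equilibrium territory sizes of about 76/(0.1·p̄) cells (~201 cells
  at the landscape mean), i.e. 12–13 km² in mean habitat, consistent with
  Chitwan home-range data; stopping at the maximum instead would triple
  territory sizes.
* **Starvation.** Death follows three consecutive months with utilized prey
  below the minimum. A freshly settled female cannot reach a minimum-size
  territory in three months under the 48-cell growth cap, so the counter
  becomes lethal only once she has been settled longer than six months (the
  time to assemble ~201 cells, plus margin). Without this establishment
  grace every settler dies and no population persists; with an unbounded
  grace, squatters on tiny territories never die and the population
  inflates. Six months is the smallest integer exceeding the assembly time.
* **Dominance and challenges.** Female border contests are initiated only by
  the older female (ties by id). Male challenge outcomes weight a triangular
  prime-age strength curve — 1 at 3 y rising to 2 at 5 y, flat to 9 y,
  declining to 1 at 12 y — the standard reading of "win probability based on
  age".
* **Male movement.** Males have no continuous movement model: a breeding
  male sits at the centroid of his females' territories; a dispersing male
  makes one jump per month to the nearest reachable target. Unassociated
  settled females are strictly preferred over challengeable incumbents;
  challenges therefore arise only from genuine male surplus. (Allowing
  nearest-of-either-kind produced perpetual challenge "ping-pong" between
  two males over the same females, and the resulting monthly infanticide
  prevented any cub cohort from surviving.)
* **Interbirth interval.** Females with living dependent offspring do not
  conceive, which produces an emergent ~24-month interbirth interval
  matching offspring independence at two years.
* **Unsettled breeding females** use the transient-female survival (0.7),
  the analogue of the dispersing-male rate; there is no separate field
  estimate for dispersing females.
* **Depletion combination.** Where primary and secondary effect zones
  overlap, the smaller (more depleted) multiplier wins; this reproduces
  "zero on any road" for cells carrying either class.
* **Mortality attribution.** Every death is tagged with the road class
  intersecting the female's territory at death; her dependents inherit the
  tag. Males (who hold no cells) are tagged `none` but stay in the
  denominator of mortality proportions.

## Synthetic landscape

The generator emulates the printed summary statistics of the real layers,
not their geometry. Prey is low-pass-filtered Gaussian noise shaped by a
smooth envelope — a broad interior "park core" plus a narrower high-prey
corridor reaching the northern edge — and mapped through a power transform
whose exponent is solved by bisection so the landscape mean is exactly
3.78 kg/month with range [0, 10.46]. Primary trunk roads hug the northern
and southern peripheries; secondary roads are denser low-prey-seeking lines
confined to the same peripheral bands; polyline lengths are trimmed to land
on the 723 km secondary and 173 km primary targets (the 25 km railway, when
enabled, brings primary infrastructure to the printed 198 km total without
altering the existing network). The resulting road-effect zone covers ~44%
of cells with mean prey 2.90 near roads versus 4.47 far — matching the
printed 2.89 / 4.3 stratification. The optional railway parallels the
northern trunk road ~1.5 km south, clipping the corridor: attractive
habitat where settling is lethal once mortality is active (the ecological
trap configuration).

What the synthetic landscape does *not* emulate: the real park's geometry,
rivers and land-cover classes, the actual OpenStreetMap road topology, and
the absolute carrying capacity of Chitwan. Baseline equilibria here are
~95–100 adults rather than ~133, so passing tests demonstrate the model's
mechanisms and their interactions, not the real-park magnitudes; those
require the user-supplied Chitwan layers, which are read through the same
interfaces.

## Numerical choices

* Distance fields are exact Euclidean distance transforms between cell
  centers (`scipy.ndimage.distance_transform_edt`), not chamfer
  approximations; an absent road class yields an infinite distance and a
  unit depletion multiplier.
* Greedy expansion uses a max-heap keyed by (effective prey, uniform random
  tie-break); all iterations over cell sets that touch the RNG or float
  accumulation run in sorted order so cloned states replay identically.
* Territory prey sums are maintained incrementally; the depletion switch
  rebinds the effective prey field and recomputes sums in sorted order
  (skipped bit-exactly when depletion changes nothing, e.g. on a roadless
  landscape).
* Rank-sum comparisons use the exact null distribution when the pooled
  sample is tie-free and the tie-corrected normal approximation otherwise;
  identical samples report p = 1. Confidence intervals are
  mean ± t₀.₉₇₅,ₙ₋₁·sd/√n.
* Rasterization marks a cell as road when a polyline segment crosses the
  cell interior (DE-9IM interior-interior predicate); collisions resolve to
  the higher class.

## Problem sizes

The default experiment reproduces the published design: 28 replicates,
600-month burn-in, 240-month horizon, four arms, on the full 170×160
synthetic landscape (~5 minutes total via shared burn-ins). Monte-Carlo
parameter-recovery checks use 10⁴ simulated females × 12 months for
survival, 10⁵ draws for litter sizes, and 2×10⁴ simulated challenges for
contest and infanticide rates. Occupancy analyses use all 28 replicates (the
published maps used 10). The README's worked example uses a reduced 80×80
landscape with proportionally scaled road-length targets.

## Known limitations

Prey biomass is static (no seasonality or predation feedback); roads do not
block movement or fragment gene flow (connectivity effects are out of
scope); males suffer no road mortality; transients have no explicit
movement; the challenge strength curve and starvation lag are documented
stand-ins where field estimates do not exist. Replicates are pseudo-
independent through consecutive seeds of the same generator family.
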