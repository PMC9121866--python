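# tigersim

Spatially explicit agent-based simulation of how transport infrastructure
(roads and a proposed railway) affects a territorial tiger (*Panthera
tigris*) population, patterned on Nepal's Chitwan National Park. The tool is
aimed at conservation planners and quantitative ecologists who want to
forecast population-level consequences of road and railway alignments before
they are built.

## The model

Tigers live on a 250 m grid carrying a static monthly rate of prey biomass
production `P_c` (kg/month per cell). Each individual follows a full life
cycle in monthly steps — cub (<1 y), juvenile (1–2 y), transient (2–3 y),
breeding (3+ y) — with the age-class survival, fecundity, litter-size and
dispersal parameters estimated from long-term Chitwan field studies.
Breeding females acquire exclusive, contiguous territories by greedily
annexing the richest frontier cells (at most 48 cells ≈ 3 km² per month)
until the prey they can utilize,

```
U = 0.1 · Σ_{c ∈ territory} P_c ,
```

meets a basal requirement of 76 kg/month (never exceeding the 167.3 kg/month
a female can use). Neighboring females contest border patches (takeover
probability 0.25, dominance by age); a female chronically below the minimum
starves. Breeding males hold up to six females within a 3 km search radius
and fight dispersing males for them; lost challenges kill (challenger 0.25,
incumbent 0.6) and takeovers trigger infanticide of dependent young (cubs
0.79, juveniles 0.24).

Infrastructure acts through two switchable mechanisms:

* **Mortality** — a breeding female whose territory contains a primary
  road/railway cell has her annual survival cut from 0.9 to 0.297; a
  secondary road cuts it to 0.81 (the larger decline wins when both apply).
  Males suffer no transportation-induced mortality.
* **Prey depletion** — effective prey is zero on infrastructure and
  recovers linearly with distance, reaching the undisturbed level at 5 km
  from primary roads/railway and 2 km from secondary roads:
  `P'_c = P_c · min(d_c / D_class, 1)`.

An experiment initializes 14 females and 7 males, burns in for 600 months
with roads present but inert, switches the configured mechanisms on
instantaneously at month 601, and records 240 experiment months (20 years).
Outputs are monthly population series (adults, breeding females, dependent
offspring) with t-based 95% confidence intervals across replicates, a death
log attributing each female's death to the road class intersecting her
territory, and per-cell occupancy maps stratified into near-road (≤2 km
secondary / ≤5 km primary) and far strata.

A synthetic-landscape generator reproduces the printed summary statistics of
the Chitwan layers (prey 0–10.46 kg/month, mean 3.78; near-road mean prey
≈2.9 vs ≈4.5 far; ~198 km primary roads including the railway, ~723 km
secondary), so every experiment runs without any data download. Real layers
(an ESRI ASCII prey raster plus a GeoJSON road network tagged
`road_class: primary|secondary`) plug into the same interfaces.

## Worked example

Four experiment arms on a reduced synthetic landscape (8 replicates sharing
burn-ins; ~40 s):

```python
import numpy as np
from tigersim import (ScenarioConfig, run_experiment_suite, near_road_mask,
                      occupancy, total_deaths_comparison)
from tigersim.engine import build_landscape

config = ScenarioConfig(
    landscape={"synthetic": {"nrows": 80, "ncols": 80, "primary_km": 55.0,
                             "railway_km": 10.0, "secondary_km": 180.0,
                             "seed": 0}},
    burn_in_steps=300, experiment_steps=240, replicates=8, base_seed=0)
landscape = build_landscape(config)
results = run_experiment_suite(config, landscape=landscape)

near = near_road_mask(landscape[1])
for arm in ("baseline", "depletion", "mortality", "depletion_mortality"):
    records = results[arm]
    end_adults = np.mean([r.adults[-1] for r in records])
    occ = occupancy(records, near_mask=near)
    print(f"{arm:>20}: {end_adults:6.1f} adults after 20 y | "
          f"occupancy near roads {occ['near_mean']:.2f}, far {occ['far_mean']:.2f}")

test = total_deaths_comparison(
    [r.adults[-1] for r in results["baseline"]],
    [r.adults[-1] for r in results["mortality"]])
print(f"baseline vs mortality: medians {test['median_a']:.0f} / "
      f"{test['median_b']:.0f}, rank-sum p = {test['p_value']:.4f}")
```

which prints:

```
            baseline:   23.0 adults after 20 y | occupancy near roads 0.45, far 0.49
           depletion:   13.1 adults after 20 y | occupancy near roads 0.15, far 0.51
           mortality:    6.6 adults after 20 y | occupancy near roads 0.10, far 0.24
 depletion_mortality:    8.1 adults after 20 y | occupancy near roads 0.09, far 0.40
baseline vs mortality: medians 22 / 6, rank-sum p = 0.0009
```

Road mortality depresses the population everywhere (occupancy falls near
*and* far from roads, because vacancies near roads keep drawing settlers
from the whole landscape); prey depletion concentrates its effect near
infrastructure and, combined with mortality, *dampens* the mortality effect
by shifting tigers away from roads before they can be killed there — the
model's central interaction.

A command-line interface wraps the same machinery:

```bash
tigersim landscape synth --out land/            # synthetic layers
tigersim simulate --scenario mortality --replicates 4 --seed 0 --out runs/
tigersim burnin-check --seed 0                  # quasi-stationarity diagnostics
tigersim report --runs runs/ --out summary.csv
```

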