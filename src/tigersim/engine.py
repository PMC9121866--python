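"""Simulation engine: monthly scheduler, burn-in/activation protocol, and
replicate runner.

A run initializes 14 females and 7 males on the landscape, burns in for 600
months with roads present but inert (no mortality adjustment, no prey
depletion), then switches the configured mechanisms on instantaneously and
records 240 experiment months.  Each month executes a fixed event order:

1. age/stage advance;
2. survival draws (road-adjusted for territory females), starvation, orphan
   deaths;
3. release of dead owners' cells and broken associations;
4. female settlement and territory expansion (with border contests);
5. male range assembly, dispersal jumps, challenges and infanticide;
6. conception, gestation, births;
7. metric recording (counts every step; occupancy during the experiment).

Deaths preceding settlement lets vacancies created by road mortality be
recolonized within the same month.  A single RNG stream per replicate is
consumed in scheduler order, so a run is a pure function of (config, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from .agents import Params, Stage, Tiger, advance_age
from .demography import (DeathEvent, apply_mortality, reproduce,
                         resolve_challenge)
from .landscape import (PreyGrid, RoadLayer, apply_depletion, load_prey_raster,
                        load_road_geojson, rasterize_roads,
                        road_layer_from_raster)
from .territory import (TerritoryMap, assemble_male_range, expand_territory,
                        find_settlement_site, male_dispersal_target)

__all__ = ["ScenarioConfig", "RunRecord", "SimulationState", "MECHANISM_ARMS",
           "build_landscape", "init_state", "step", "run_scenario",
           "run_replicates", "run_experiment_suite"]

#: canonical experiment arms, keyed by name
MECHANISM_ARMS = {
    "baseline": frozenset(),
    "depletion": frozenset({"depletion"}),
    "mortality": frozenset({"mortality"}),
    "depletion_mortality": frozenset({"depletion", "mortality"}),
}


@dataclass
class ScenarioConfig:
    """Scenario: road configuration x mechanism switches x run settings."""

    road_config: str = "existing"          # or "existing_plus_railway"
    mechanisms: frozenset = frozenset()    # subset of {"mortality", "depletion"}
    burn_in_steps: int = 600
    experiment_steps: int = 240
    n_females_init: int = 14
    n_males_init: int = 7
    replicates: int = 28
    base_seed: int = 0
    landscape: dict = dc_field(default_factory=dict)
    params: Params = dc_field(default_factory=Params)

    def __post_init__(self) -> None:
        if self.road_config not in ("existing", "existing_plus_railway"):
            raise ValueError(f"unknown road_config: {self.road_config}")
        self.mechanisms = frozenset(self.mechanisms)
        if not self.mechanisms <= {"mortality", "depletion"}:
            raise ValueError(f"unknown mechanisms: {set(self.mechanisms)}")
        if self.burn_in_steps < 0 or self.replicates < 1:
            raise ValueError("burn_in_steps must be >= 0 and replicates >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = Params.from_dict(raw.pop("params", {}))
        scenario = raw.pop("scenario", {})
        landscape = raw.pop("landscape", {})
        mechanisms = frozenset(scenario.pop("mechanisms", []))
        return cls(mechanisms=mechanisms, landscape=landscape, params=params,
                   **scenario)

    def to_yaml(self, path) -> None:
        data = {
            "scenario": {
                "road_config": self.road_config,
                "mechanisms": sorted(self.mechanisms),
                "burn_in_steps": self.burn_in_steps,
                "experiment_steps": self.experiment_steps,
                "n_females_init": self.n_females_init,
                "n_males_init": self.n_males_init,
                "replicates": self.replicates,
                "base_seed": self.base_seed,
            },
            "landscape": self.landscape,
            "params": self.params.to_dict(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class RunRecord:
    """Per-step population counts, the death log, and the occupancy
    accumulator for one replicate."""

    seed: int
    scenario: dict
    burn_in_steps: int
    experiment_steps: int
    steps: list = dc_field(default_factory=list)
    adults: list = dc_field(default_factory=list)
    breeding_females: list = dc_field(default_factory=list)
    dependents: list = dc_field(default_factory=list)
    deaths: list = dc_field(default_factory=list)
    occupancy_counts: np.ndarray | None = None
    occupancy_steps: int = 0
    covered_cells: list = dc_field(default_factory=list)  # per experiment step
    extinct_during_burn_in: bool = False

    @property
    def counts(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": self.steps,
            "adults": self.adults,
            "breeding_females": self.breeding_females,
            "dependents": self.dependents,
        })

    @property
    def deaths_df(self) -> pd.DataFrame:
        cols = ["step", "tiger_id", "sex", "stage", "cause", "road_intersect"]
        rows = [(d.step, d.tiger_id, d.sex, d.stage, d.cause, d.road_intersect)
                for d in self.deaths]
        return pd.DataFrame(rows, columns=cols)

    @property
    def occupancy(self) -> np.ndarray:
        """Per-cell proportion of experiment steps with a breeding female's
        territory on the cell."""
        if self.occupancy_counts is None or self.occupancy_steps == 0:
            raise ValueError("no occupancy recorded")
        return self.occupancy_counts / self.occupancy_steps

    def experiment_counts(self) -> pd.DataFrame:
        return self.counts[self.counts["step"] > self.burn_in_steps].reset_index(drop=True)


class SimulationState:
    """Mutable simulation state for one replicate."""

    def __init__(self, prey: PreyGrid, roads: RoadLayer, params: Params,
                 rng: np.random.Generator, record: RunRecord):
        self.prey = prey
        self.roads = roads
        self.params = params
        self.rng = rng
        self.record = record
        self.tmap = TerritoryMap(prey.production, prey.mask, prey.cell_size,
                                 road_class=roads.class_grid)
        self.tigers: dict[int, Tiger] = {}
        self.next_id = 1
        self.step_idx = 0
        self.mechanisms_active: set = set()
        self.recording = False
        self._natal_mask_cache: dict[int, np.ndarray] = {}

    def new_tiger(self, sex: str, age: int, mother_id: int | None = None,
                  natal_center: tuple[int, int] | None = None) -> Tiger:
        t = Tiger(self.next_id, sex, age, mother_id, natal_center)
        self.tigers[t.id] = t
        self.next_id += 1
        return t

    def clone(self) -> "SimulationState":
        """Snapshot for branching experiment arms off a shared burn-in."""
        new = SimulationState.__new__(SimulationState)
        new.prey = self.prey
        new.roads = self.roads
        new.params = self.params
        rng = np.random.Generator(np.random.PCG64())
        rng.bit_generator.state = self.rng.bit_generator.state
        new.rng = rng
        new.record = copy.deepcopy(self.record)
        new.tmap = self.tmap.copy()
        new.tigers = {tid: _clone_tiger(t) for tid, t in self.tigers.items()}
        new.next_id = self.next_id
        new.step_idx = self.step_idx
        new.mechanisms_active = set(self.mechanisms_active)
        new.recording = self.recording
        new._natal_mask_cache = {}
        return new


def _clone_tiger(t: Tiger) -> Tiger:
    new = Tiger(t.id, t.sex, t.age, t.mother_id, t.natal_center)
    new.stage = t.stage
    new.territory_id = t.territory_id
    new.associated_male_id = t.associated_male_id
    new.female_ids = list(t.female_ids)
    new.gestation_remaining = t.gestation_remaining
    new.alive = t.alive
    new.location = t.location
    new.months_below_min = t.months_below_min
    new.has_met_min = t.has_met_min
    new.settled_months = t.settled_months
    return new


# ---------------------------------------------------------------------------
# Landscape assembly and initialization
# ---------------------------------------------------------------------------


def build_landscape(config: ScenarioConfig) -> tuple[PreyGrid, RoadLayer]:
    """Materialize the landscape described by the config: either synthetic
    (default) or user-supplied prey/road files read through the standard
    interfaces."""
    from . import synthetic_landscape as synth

    spec = config.landscape or {}
    if "prey_raster" in spec:
        prey = load_prey_raster(spec["prey_raster"])
        include_railway = config.road_config == "existing_plus_railway"
        if "roads_geojson" in spec:
            geoms = load_road_geojson(spec["roads_geojson"])
            if not include_railway and "railway_geojson" not in spec:
                pass  # a plain file is taken as the requested configuration
            if include_railway and "railway_geojson" in spec:
                geoms = geoms + load_road_geojson(spec["railway_geojson"])
            roads = rasterize_roads(geoms, prey)
        elif "roads_raster" in spec:
            roads = road_layer_from_raster(spec["roads_raster"], prey.cell_size)
        else:
            raise ValueError("landscape config needs roads_geojson or roads_raster")
        return prey, roads
    synth_spec = synth.SynthSpec.from_dict(spec.get("synthetic", {}))
    return synth.generate_landscape(
        synth_spec, railway=config.road_config == "existing_plus_railway")


def init_state(prey: PreyGrid, roads: RoadLayer, config: ScenarioConfig,
               seed: int) -> SimulationState:
    """Initial population: 14 female origins sampled pairwise >= 2 km apart
    from cells above the 60th prey percentile (ages uniform 36-120 months),
    and 7 males placed on distinct female origins.  The burn-in washes out
    these choices."""
    rng = np.random.default_rng(seed)
    record = RunRecord(seed=seed, scenario={
        "road_config": config.road_config,
        "mechanisms": sorted(config.mechanisms),
    }, burn_in_steps=config.burn_in_steps,
        experiment_steps=config.experiment_steps)
    state = SimulationState(prey, roads, config.params, rng, record)
    state.record.occupancy_counts = np.zeros(prey.shape, dtype=np.int32)

    prod = prey.production[prey.mask]
    thresh = np.quantile(prod, 0.6)
    cand = np.argwhere(prey.mask & (prey.production >= thresh))
    order = rng.permutation(len(cand))
    chosen: list[tuple[int, int]] = []
    min_sep = config.params.settlement_radius_ideal / prey.cell_size
    for idx in order:
        r, c = map(int, cand[idx])
        if all(np.hypot(r - rr, c - cc) > min_sep for rr, cc in chosen):
            chosen.append((r, c))
        if len(chosen) == config.n_females_init:
            break

    for origin in chosen:
        age = int(rng.integers(36, 121))
        f = state.new_tiger("F", age, natal_center=origin)
        f.location = origin
        state.tmap.settle(f.id, origin)
        f.territory_id = f.id
    male_origins = [chosen[i] for i in
                    rng.choice(len(chosen), size=min(config.n_males_init, len(chosen)),
                               replace=False)]
    for origin in male_origins:
        age = int(rng.integers(36, 121))
        state.new_tiger("M", age, natal_center=origin)
    state.mechanisms_active = set()
    return state


# ---------------------------------------------------------------------------
# The monthly step
# ---------------------------------------------------------------------------


def _natal_mask(state: SimulationState, female: Tiger) -> np.ndarray:
    key = female.natal_center
    cached = state._natal_mask_cache.get(key)
    if cached is None:
        tmap = state.tmap
        r0, c0 = key
        d = np.hypot(tmap._rows - r0, tmap._cols - c0) * tmap.cell_size
        cached = tmap.mask & (d <= state.params.max_dispersal_female)
        state._natal_mask_cache[key] = cached
    return cached


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation exactly one month (see module docstring for the
    event order)."""
    state.step_idx += 1
    tigers, tmap, params, rng = state.tigers, state.tmap, state.params, state.rng

    # (1) age and stage advance
    for tid in sorted(tigers):
        advance_age(tigers[tid])

    # (2) mortality: background + road-adjusted + starvation + orphans
    events = apply_mortality(tigers, tmap, state.roads, state.mechanisms_active,
                             params, rng, state.step_idx)
    state.record.deaths.extend(events)

    # (3) release cells and associations of the dead
    dead = [tigers[tid] for tid in sorted(tigers) if not tigers[tid].alive]
    for t in dead:
        if t.sex == "F":
            if t.territory_id is not None:
                tmap.release(t.territory_id)
            if t.associated_male_id is not None:
                m = tigers.get(t.associated_male_id)
                if m is not None and t.id in m.female_ids:
                    m.female_ids.remove(t.id)
        else:
            for fid in t.female_ids:
                f = tigers.get(fid)
                if f is not None:
                    f.associated_male_id = None
    for t in dead:
        del tigers[t.id]

    # (4) female settlement, then expansion with contests
    unsettled = [tigers[tid] for tid in sorted(tigers)
                 if tigers[tid].sex == "F" and tigers[tid].stage == Stage.BREEDING
                 and tigers[tid].territory_id is None]
    occ_dist = None
    for f in unsettled:
        if occ_dist is None:
            occ_dist = tmap.distance_to_owned()
        site = find_settlement_site(f, tmap, params, rng, occ_dist=occ_dist,
                                    natal_ok=_natal_mask(state, f))
        if site is not None:
            tmap.settle(f.id, site)
            f.territory_id = f.id
            f.location = site
            occ_dist = None  # owned set changed
    for tid in sorted(tigers):
        f = tigers[tid]
        if f.sex != "F" or f.territory_id is None:
            continue
        terr = tmap.territories[f.territory_id]
        if terr.utilized_prey(params) < params.prey_min_threshold:
            expand_territory(f, tmap, params, rng, tigers)

    # (5) males: locations, range assembly, dispersal jumps, challenges
    challenge_deaths: list[DeathEvent] = []
    for tid in sorted(tigers):
        m = tigers[tid]
        if m.sex != "M" or m.stage != Stage.BREEDING or not m.alive:
            continue
        if m.female_ids:
            cells = [tmap.territories[fid].centroid_cell
                     for fid in m.female_ids if fid in tmap.territories]
            if cells:
                m.location = (int(round(np.mean([c[0] for c in cells]))),
                              int(round(np.mean([c[1] for c in cells]))))
            assemble_male_range(m, tigers, tmap, params)
        else:
            if m.location is None:
                m.location = m.natal_center
            _, challenges = assemble_male_range(m, tigers, tmap, params)
            if m.female_ids:
                continue
            incumbent = None
            target = male_dispersal_target(m, tigers, tmap, params)
            if target is not None and target[1] == "female":
                m.location = target[0]
                assemble_male_range(m, tigers, tmap, params)
            elif challenges:
                incumbent = tigers.get(challenges[0][2])
            elif target is not None:
                m.location = target[0]
                incumbent = tigers.get(target[2])
            if incumbent is not None and incumbent.alive and incumbent.female_ids:
                out = resolve_challenge(m, incumbent, tigers, tmap, params, rng,
                                        state.step_idx)
                challenge_deaths.extend(out.deaths)
    if challenge_deaths:
        state.record.deaths.extend(challenge_deaths)
        for tid in sorted(tigers):
            if not tigers[tid].alive:
                del tigers[tid]

    # (6) conception, gestation, births
    def spawn(mother: Tiger, size: int, sexes: list) -> None:
        natal = tmap.territories[mother.territory_id].centroid_cell
        for sex in sexes:
            state.new_tiger(sex, 0, mother_id=mother.id, natal_center=natal)

    reproduce(tigers, tmap, params, rng, state.step_idx, spawn)

    # (7) record
    rec = state.record
    rec.steps.append(state.step_idx)
    rec.adults.append(sum(1 for t in tigers.values() if t.stage == Stage.BREEDING))
    rec.breeding_females.append(
        sum(1 for t in tigers.values() if t.sex == "F" and t.territory_id is not None))
    rec.dependents.append(sum(1 for t in tigers.values() if t.is_dependent))
    if state.recording:
        owned = tmap.owner > 0
        rec.occupancy_counts += owned.astype(np.int32)
        rec.occupancy_steps += 1
        rec.covered_cells.append(int(owned.sum()))
    return state


def activate_mechanisms(state: SimulationState, mechanisms: frozenset) -> None:
    """Switch the configured mechanisms on instantaneously.

    Depletion rewrites the effective prey grid once (prey is static, so the
    depleted field holds for the rest of the run) and territory prey sums are
    re-evaluated against it; the mortality switch takes effect from the next
    survival draw.  Consumes no randomness.
    """
    if "depletion" in mechanisms:
        depleted = apply_depletion(state.prey, state.roads)
        # skip the rebind when depletion changes nothing (roadless landscape)
        # so the run stays bit-identical to the baseline under a shared seed
        if not np.array_equal(depleted.production, state.tmap.effective_prey):
            state.tmap.set_effective_prey(depleted.production)
    state.mechanisms_active = set(mechanisms)


def _run_burn_in(state: SimulationState, config: ScenarioConfig) -> None:
    for _ in range(config.burn_in_steps):
        step(state)
    if not state.tigers:
        state.record.extinct_during_burn_in = True


def _run_experiment(state: SimulationState, config: ScenarioConfig) -> RunRecord:
    activate_mechanisms(state, config.mechanisms)
    state.recording = True
    for _ in range(config.experiment_steps):
        step(state)
    return state.record


def run_scenario(config: ScenarioConfig, seed: int | None = None,
                 landscape: tuple[PreyGrid, RoadLayer] | None = None) -> RunRecord:
    """Run one replicate: burn-in with inert roads, instantaneous activation,
    then the recorded experiment horizon."""
    if seed is None:
        seed = config.base_seed
    prey, roads = landscape if landscape is not None else build_landscape(config)
    state = init_state(prey, roads, config, seed)
    _run_burn_in(state, config)
    return _run_experiment(state, config)


def run_replicates(config: ScenarioConfig,
                   landscape: tuple[PreyGrid, RoadLayer] | None = None) -> list[RunRecord]:
    """Independent replicates; replicate r uses seed = base_seed + r."""
    if landscape is None:
        landscape = build_landscape(config)
    return [run_scenario(config, seed=config.base_seed + r, landscape=landscape)
            for r in range(config.replicates)]


def run_experiment_suite(config: ScenarioConfig, arms: list[str] | None = None,
                         landscape: tuple[PreyGrid, RoadLayer] | None = None,
                         ) -> dict[str, list[RunRecord]]:
    """Run all experiment arms over shared burn-ins.

    Mechanisms are inert during burn-in, so arms of the same replicate share
    the burn-in trajectory bit-exactly; the state is branched at activation.
    Returns {arm name: [RunRecord per replicate]}.
    """
    if arms is None:
        arms = list(MECHANISM_ARMS)
    if landscape is None:
        landscape = build_landscape(config)
    prey, roads = landscape
    results: dict[str, list[RunRecord]] = {arm: [] for arm in arms}
    for r in range(config.replicates):
        seed = config.base_seed + r
        state = init_state(prey, roads, config, seed)
        _run_burn_in(state, config)
        for arm in arms:
            arm_config = copy.copy(config)
            arm_config.mechanisms = MECHANISM_ARMS[arm]
            branch = state.clone()
            branch.record.scenario = {"road_config": config.road_config,
                                      "mechanisms": sorted(MECHANISM_ARMS[arm])}
            results[arm].append(_run_experiment(branch, arm_config))
    return results
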