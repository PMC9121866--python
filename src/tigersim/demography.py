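"""Monthly demography: survival (with road adjustment), starvation,
reproduction, male challenges and infanticide, and orphan mortality.

All rates in the parameter bundle are annual; the model steps monthly, so an
annual survival ``s`` becomes the per-month probability ``s**(1/12)`` (the
12th root preserves the compounded annual rate exactly) and an annual
breeding probability ``p`` becomes the per-eligible-month hazard
``1 - (1 - p)**(1/12)``.

The road-mortality mechanism acts only on breeding females: a female whose
territory contains any primary-road/railway cell has her annual survival
replaced by 0.297, any secondary-road cell (and no primary) by 0.81; males
suffer no transportation-induced mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import Params, Stage, Tiger
from .landscape import CLASS_NONE, CLASS_PRIMARY, CLASS_SECONDARY, RoadLayer
from .territory import Territory, TerritoryMap

__all__ = ["DeathEvent", "road_adjusted_annual_survival", "monthly_survival",
           "conception_hazard", "apply_mortality", "check_starvation",
           "reproduce", "resolve_challenge", "challenge_weight",
           "ChallengeOutcome"]

ROAD_CLASS_NAMES = {CLASS_NONE: "none", CLASS_SECONDARY: "secondary",
                    CLASS_PRIMARY: "primary"}


@dataclass
class DeathEvent:
    """One death, annotated with the territory-road intersection at death.

    ``road_intersect`` records, for a territory-holding female (and for her
    dependents), whether her territory contained a primary or secondary road
    cell when she died.
    """

    tiger_id: int
    step: int
    cause: str                 # background | road_enhanced | starvation |
                               # challenge | infanticide | orphaned
    road_intersect: str        # none | secondary | primary
    stage: str
    sex: str


def _territory_road_class(territory: Territory, road_layer: RoadLayer | None) -> int:
    """Road class intersected by a territory.  Uses the territory's
    incrementally maintained road-cell counters when they are bound to a road
    grid, otherwise recomputes from the given layer."""
    if territory.n_primary > 0:
        return CLASS_PRIMARY
    if territory.n_secondary > 0:
        return CLASS_SECONDARY
    if road_layer is not None:
        classes = {int(road_layer.class_grid[rc]) for rc in territory.cells}
        if CLASS_PRIMARY in classes:
            return CLASS_PRIMARY
        if CLASS_SECONDARY in classes:
            return CLASS_SECONDARY
    return CLASS_NONE


def road_adjusted_annual_survival(base: float, territory: Territory,
                                  road_layer: RoadLayer | None,
                                  mechanism_on: bool,
                                  params: Params | None = None) -> float:
    """Annual survival of a territory-holding female under the road-mortality
    mechanism: 0.297 with any primary road/railway cell in the territory,
    0.81 with only secondary road cells, the base rate otherwise (or with the
    mechanism off).  When both classes intersect, the larger decline (the
    primary one) applies."""
    if params is None:
        params = Params()
    if not mechanism_on:
        return base
    cls = _territory_road_class(territory, road_layer)
    if cls == CLASS_PRIMARY:
        return params.road_survival_primary
    if cls == CLASS_SECONDARY:
        return params.road_survival_secondary
    return base


def monthly_survival(annual: float) -> float:
    """Per-month survival from an annual rate: annual**(1/12).

    Zero is allowed (certain death within the month); negative rates are
    rejected.
    """
    if annual < 0:
        raise ValueError("annual survival must be non-negative")
    return annual ** (1.0 / 12.0)


def conception_hazard(annual_prob: float) -> float:
    """Per-eligible-month conception hazard from an annual breeding
    probability: 1 - (1 - p)**(1/12)."""
    return 1.0 - (1.0 - annual_prob) ** (1.0 / 12.0)


def check_starvation(female: Tiger, utilized_prey: float, params: Params) -> bool:
    """Advance the female's consecutive-months-below-minimum counter.

    The counter increments when utilized prey is below the 76 kg/month
    minimum and resets otherwise; starvation kills at three consecutive
    months.  Returns True when the counter reaches the threshold.
    """
    if utilized_prey < params.prey_min_threshold:
        female.months_below_min += 1
    else:
        female.months_below_min = 0
        female.has_met_min = True
    return female.months_below_min >= params.starvation_months


def apply_mortality(tigers: dict, tmap: TerritoryMap,
                    road_layer: RoadLayer | None, mechanisms: set,
                    params: Params, rng: np.random.Generator,
                    step: int) -> list[DeathEvent]:
    """One month of survival draws for every living tiger.

    Breeding females with territories use the road-adjusted annual rate;
    everyone else uses the class-specific base rate.  Starvation is checked
    for territory-holding females (the consecutive-month counter becomes
    lethal only once a female has met the minimum at least once, so that
    females still building a first territory are not starved by the growth
    cap).  Dependent offspring of any female who died this step die too
    (cause ``orphaned``), inheriting her road-intersection tag.

    Deaths are recorded as events; the caller removes the dead and releases
    their cells.
    """
    mechanism_on = "mortality" in mechanisms
    ids = sorted(tid for tid, t in tigers.items() if t.alive)
    draws = rng.random(len(ids))
    events: list[DeathEvent] = []
    died_mothers: dict[int, str] = {}

    for tid, u in zip(ids, draws):
        t = tigers[tid]
        road_tag = "none"
        cause = "background"
        if t.sex == "F" and t.territory_id is not None:
            terr = tmap.territories[t.territory_id]
            annual = road_adjusted_annual_survival(
                params.survival_breeding_female, terr, road_layer,
                mechanism_on, params)
            road_tag = ROAD_CLASS_NAMES[_territory_road_class(terr, road_layer)]
            if mechanism_on and annual < params.survival_breeding_female:
                cause = "road_enhanced"
        else:
            annual = params.annual_survival(t)
        if u >= monthly_survival(annual):
            t.alive = False
            events.append(DeathEvent(t.id, step, cause, road_tag,
                                     t.stage.name.lower(), t.sex))
            if t.sex == "F":
                died_mothers[t.id] = road_tag

    # starvation among surviving territory holders; females still within the
    # establishment grace period accumulate the counter but do not die yet
    for tid in ids:
        t = tigers[tid]
        if not t.alive or t.sex != "F" or t.territory_id is None:
            continue
        t.settled_months += 1
        terr = tmap.territories[t.territory_id]
        starved = check_starvation(t, terr.utilized_prey(params), params)
        if starved and t.settled_months > params.starvation_grace_months:
            t.alive = False
            road_tag = ROAD_CLASS_NAMES[_territory_road_class(terr, road_layer)]
            events.append(DeathEvent(t.id, step, "starvation", road_tag,
                                     t.stage.name.lower(), t.sex))
            died_mothers[t.id] = road_tag

    # orphans: dependents die with their mother, in the same step
    if died_mothers:
        for tid in ids:
            t = tigers[tid]
            if t.alive and t.is_dependent and t.mother_id in died_mothers:
                t.alive = False
                events.append(DeathEvent(t.id, step, "orphaned",
                                         died_mothers[t.mother_id],
                                         t.stage.name.lower(), t.sex))
    return events


def reproduce(tigers: dict, tmap: TerritoryMap, params: Params,
              rng: np.random.Generator, step: int, spawn) -> list[int]:
    """Monthly conception, gestation, and births.

    A territory-holding female with a living associated male, no living
    dependent offspring, and no current pregnancy conceives with the monthly
    hazard of her age-specific annual breeding probability (0.9 at age three,
    1.0 at four plus, which makes conception certain in the first eligible
    month).  Gestation is 3 or 4 months with equal probability; at term,
    ``spawn(mother, size, sexes)`` creates the litter.  Returns ids of
    mothers that gave birth this step.
    """
    dependents_of: set[int] = set()
    for t in tigers.values():
        if t.alive and t.is_dependent and t.mother_id is not None:
            dependents_of.add(t.mother_id)

    from .agents import sample_litter

    births: list[int] = []
    for tid in sorted(tigers):
        f = tigers[tid]
        if not (f.alive and f.sex == "F" and f.stage == Stage.BREEDING
                and f.territory_id is not None):
            continue
        if f.gestation_remaining > 0:
            f.gestation_remaining -= 1
            if f.gestation_remaining == 0:
                size, sexes = sample_litter(rng, params)
                spawn(f, size, sexes)
                births.append(f.id)
            continue
        male = tigers.get(f.associated_male_id) if f.associated_male_id else None
        if male is None or not male.alive:
            continue
        if f.id in dependents_of:
            continue
        p_annual = params.fecundity_age3 if f.age < 48 else params.fecundity_age4plus
        if rng.random() < conception_hazard(p_annual):
            f.gestation_remaining = int(rng.choice(params.gestation_months))
    return births


def challenge_weight(age_months: int) -> float:
    """Prime-age strength for male challenges: 1 at 3 years, rising linearly
    to 2 at 5 years, flat through 9, declining to 1 at 12+ years."""
    y = age_months / 12.0
    if y <= 3.0:
        return 1.0
    if y < 5.0:
        return 1.0 + (y - 3.0) / 2.0
    if y <= 9.0:
        return 2.0
    if y < 12.0:
        return 2.0 - (y - 9.0) / 3.0
    return 1.0


@dataclass
class ChallengeOutcome:
    challenger_won: bool
    deaths: list            # DeathEvents generated by the challenge
    transferred: list       # female ids moved to the winner


def resolve_challenge(challenger: Tiger, incumbent: Tiger, tigers: dict,
                      tmap: TerritoryMap, params: Params,
                      rng: np.random.Generator, step: int) -> ChallengeOutcome:
    """A dispersing male challenges a breeding male for his females.

    The challenger wins with probability w(c)/(w(c)+w(i)) using the prime-age
    strength curve.  On a win all females transfer; each dependent cub of a
    transferred female dies by infanticide with probability 0.79 and each
    juvenile with 0.24, and the incumbent dies with probability 0.6 (else he
    re-enters dispersal).  On a loss the challenger dies with probability
    0.25 (else he keeps dispersing).
    """
    wc, wi = challenge_weight(challenger.age), challenge_weight(incumbent.age)
    won = rng.random() < wc / (wc + wi)
    deaths: list[DeathEvent] = []
    transferred: list[int] = []

    if won:
        for fid in list(incumbent.female_ids):
            f = tigers.get(fid)
            if f is None or not f.alive:
                continue
            f.associated_male_id = challenger.id
            challenger.female_ids.append(fid)
            transferred.append(fid)
            road_tag = "none"
            if f.territory_id is not None:
                road_tag = ROAD_CLASS_NAMES[
                    _territory_road_class(tmap.territories[f.territory_id], None)]
            for tid in sorted(tigers):
                d = tigers[tid]
                if not (d.alive and d.is_dependent and d.mother_id == fid):
                    continue
                p = (params.infanticide_prob_cub if d.stage == Stage.CUB
                     else params.infanticide_prob_juvenile)
                if rng.random() < p:
                    d.alive = False
                    deaths.append(DeathEvent(d.id, step, "infanticide", road_tag,
                                             d.stage.name.lower(), d.sex))
        incumbent.female_ids = []
        challenger.location = incumbent.location
        if rng.random() < params.incumbent_death_prob:
            incumbent.alive = False
            deaths.append(DeathEvent(incumbent.id, step, "challenge", "none",
                                     incumbent.stage.name.lower(), "M"))
    else:
        if rng.random() < params.challenger_death_prob:
            challenger.alive = False
            deaths.append(DeathEvent(challenger.id, step, "challenge", "none",
                                     challenger.stage.name.lower(), "M"))
    return ChallengeOutcome(won, deaths, transferred)
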