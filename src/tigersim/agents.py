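"""Tiger individuals, age-stage structure, and the behavioral parameter bundle.

Stages follow the field's standard age classes: cub (<12 months), juvenile
(12-<24), transient (24-<36), breeding (>=36).  Ages are tracked in integer
months; "3+ years old" means >=36 months.  Cubs and juveniles are dependent
offspring: they live in their mother's territory and die with her.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import IntEnum

import numpy as np

__all__ = ["Stage", "Tiger", "Params", "stage_from_age", "advance_age",
           "sample_litter", "monthly_prey_requirement"]


class Stage(IntEnum):
    CUB = 0
    JUVENILE = 1
    TRANSIENT = 2
    BREEDING = 3


def stage_from_age(age_months: int) -> Stage:
    """Deterministic age->stage map with boundaries at 12/24/36 months."""
    if age_months < 12:
        return Stage.CUB
    if age_months < 24:
        return Stage.JUVENILE
    if age_months < 36:
        return Stage.TRANSIENT
    return Stage.BREEDING


def monthly_prey_requirement(kg_per_day: float) -> float:
    """Convert a daily consumption rate to the model's monthly requirement:
    (kg/day * 365 days) / 12 months.

    2.5 kg/day (basal metabolic rate) -> ~76 kg/month minimum;
    5.5 kg/day (observed consumption) -> ~167.3 kg/month maximum.
    """
    return kg_per_day * 365.0 / 12.0


class Tiger:
    """One tiger agent.  Position is cell-based: dependents and transients are
    book-kept at their natal center; breeding females at their territory;
    males at ``location`` (natal center until they disperse)."""

    __slots__ = (
        "id", "sex", "age", "stage", "mother_id", "natal_center", "territory_id",
        "associated_male_id", "female_ids", "gestation_remaining", "alive",
        "location", "months_below_min", "has_met_min", "settled_months",
    )

    def __init__(self, id: int, sex: str, age: int, mother_id: int | None = None,
                 natal_center: tuple[int, int] | None = None):
        self.id = id
        self.sex = sex
        self.age = age
        self.stage = stage_from_age(age)
        self.mother_id = mother_id
        self.natal_center = natal_center
        self.territory_id: int | None = None          # breeding females only
        self.associated_male_id: int | None = None    # breeding females only
        self.female_ids: list[int] = []               # breeding males only
        self.gestation_remaining = 0                  # 0 = not pregnant
        self.alive = True
        self.location = natal_center                  # males: current cell
        self.months_below_min = 0                     # starvation counter
        self.has_met_min = False                      # territory ever met minimum
        self.settled_months = 0                       # months since settlement

    @property
    def is_dependent(self) -> bool:
        return self.stage in (Stage.CUB, Stage.JUVENILE)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Tiger(id={self.id}, sex={self.sex}, age={self.age}, "
                f"stage={self.stage.name}, alive={self.alive})")


def advance_age(tiger: Tiger) -> Tiger:
    """Age one month and recompute the stage; boundaries apply exactly at
    12/24/36 months.  A tiger turning 36 months becomes breeding and (if it
    has no territory/females) enters the dispersal pool."""
    tiger.age += 1
    tiger.stage = stage_from_age(tiger.age)
    return tiger


@dataclass
class Params:
    """Behavioral and demographic parameters.

    Defaults are the Chitwan field estimates: survival/fecundity/litter rates
    from long-term monitoring, territory rules (prey thresholds, 48-cell
    monthly growth cap, 0.25 patch-takeover probability), male tenure rules,
    and the road-effect survival declines (0.9 -> 0.297 with a primary
    road/railway in the territory, 0.9 -> 0.81 with a secondary road).
    """

    # litter size pmf over 1..5 cubs
    litter_size_pmf: tuple = (0.0, 0.23, 0.58, 0.17, 0.02)

    # annual survival by class
    survival_breeding_male: float = 0.8
    survival_breeding_female: float = 0.9
    survival_dispersal_male: float = 0.65
    survival_transient_male: float = 0.65
    survival_transient_female: float = 0.7
    survival_juvenile: float = 0.9
    survival_cub: float = 0.6

    # annual probability a resident (territory-holding) female breeds
    fecundity_age3: float = 0.9
    fecundity_age4plus: float = 1.0

    # maximum dispersal distance from the natal range (m)
    max_dispersal_male: float = 66_000.0
    max_dispersal_female: float = 33_000.0

    # monthly prey thresholds within a territory (kg/month)
    prey_min_threshold: float = 76.0
    prey_max_threshold: float = 167.3
    prey_utilization: float = 0.1

    # territory dynamics
    max_cells_per_step: int = 48
    patch_takeover_prob: float = 0.25
    settlement_radius_ideal: float = 2000.0
    settlement_radius_relaxed: float = 1000.0
    settlement_score_radius: float = 1000.0

    # males
    male_search_radius: float = 3000.0
    max_females_per_male: int = 6

    # reproduction
    sex_ratio_female: float = 0.5
    gestation_months: tuple = (3, 4)

    # challenges and infanticide
    challenger_death_prob: float = 0.25
    incumbent_death_prob: float = 0.6
    infanticide_prob_cub: float = 0.79
    infanticide_prob_juvenile: float = 0.24

    # road-effect survival (annual) for breeding females
    road_survival_primary: float = 0.297
    road_survival_secondary: float = 0.81

    # starvation: consecutive months with utilized prey below the minimum
    # kill after starvation_months; a freshly settled female is exempt for
    # the months it takes to assemble a minimum territory under the 48-cell
    # growth cap (~201 cells at mean prey -> ~5 months, plus margin)
    starvation_months: int = 3
    starvation_grace_months: int = 6

    def __post_init__(self) -> None:
        if abs(sum(self.litter_size_pmf) - 1.0) > 1e-9:
            raise ValueError("litter size pmf must sum to 1")
        if not self.prey_min_threshold < self.prey_max_threshold:
            raise ValueError("prey minimum threshold must be below the maximum")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("survival_", "fecundity_", "road_survival_")) or \
                    f.name.endswith("_prob"):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{f.name} must be a probability, got {v}")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**kwargs)

    def annual_survival(self, tiger: Tiger) -> float:
        """Class-specific annual survival (before any road adjustment).

        Breeding-stage animals without a territory (females) or without
        associated females (males) use the dispersing/transient rates.
        """
        if tiger.stage == Stage.CUB:
            return self.survival_cub
        if tiger.stage == Stage.JUVENILE:
            return self.survival_juvenile
        if tiger.stage == Stage.TRANSIENT:
            return (self.survival_transient_female if tiger.sex == "F"
                    else self.survival_transient_male)
        if tiger.sex == "F":
            return (self.survival_breeding_female if tiger.territory_id is not None
                    else self.survival_transient_female)
        return (self.survival_breeding_male if tiger.female_ids
                else self.survival_dispersal_male)


def sample_litter(rng: np.random.Generator, params: Params) -> tuple[int, list[str]]:
    """Draw a litter size from the empirical pmf (sizes 1..5) and independent
    fair-coin sexes for each cub."""
    size = int(rng.choice(np.arange(1, 6), p=np.asarray(params.litter_size_pmf)))
    sexes = ["F" if rng.random() < params.sex_ratio_female else "M" for _ in range(size)]
    return size, sexes
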