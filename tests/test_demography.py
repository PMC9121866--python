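"""Monthly survival (including road adjustment), starvation, reproduction,
and male challenges with infanticide."""

import numpy as np
import pytest

from tigersim.agents import Params, Stage, Tiger
from tigersim.demography import (apply_mortality, challenge_weight,
                                 check_starvation, conception_hazard,
                                 monthly_survival, reproduce,
                                 resolve_challenge,
                                 road_adjusted_annual_survival)
from tigersim.landscape import (CLASS_PRIMARY, CLASS_SECONDARY, PreyGrid,
                                RoadLayer)
from tigersim.territory import TerritoryMap

from conftest import make_tmap, settled_female


def tmap_with_roads(shape=(30, 30), road_grid=None, prey_value=3.78):
    prey = PreyGrid(production=np.full(shape, float(prey_value)),
                    mask=np.ones(shape, dtype=bool))
    roads = RoadLayer(class_grid=road_grid if road_grid is not None
                      else np.zeros(shape, dtype=np.uint8))
    return make_tmap(prey, roads), roads


class TestRoadAdjustedSurvival:
    def build(self, road_col_class=None):
        grid = np.zeros((30, 30), dtype=np.uint8)
        if road_col_class is not None:
            grid[:, 16] = road_col_class
        tmap, roads = tmap_with_roads(road_grid=grid)
        f = settled_female(tmap, fid=1, origin=(15, 15))
        tmap._annex(tmap.territories[1], (15, 16))  # may be a road cell
        return tmap.territories[1], roads

    def test_primary_intersection(self, params):
        terr, roads = self.build(CLASS_PRIMARY)
        assert road_adjusted_annual_survival(0.9, terr, roads, True, params) == 0.297

    def test_secondary_intersection(self, params):
        terr, roads = self.build(CLASS_SECONDARY)
        assert road_adjusted_annual_survival(0.9, terr, roads, True, params) == 0.81

    def test_both_classes_larger_decline_wins(self, params):
        grid = np.zeros((30, 30), dtype=np.uint8)
        grid[:, 16] = CLASS_SECONDARY
        grid[:, 14] = CLASS_PRIMARY
        tmap, roads = tmap_with_roads(road_grid=grid)
        settled_female(tmap, fid=1, origin=(15, 15))
        terr = tmap.territories[1]
        tmap._annex(terr, (15, 16))
        tmap._annex(terr, (15, 14))
        assert road_adjusted_annual_survival(0.9, terr, roads, True, params) == 0.297

    def test_mechanism_off_or_no_road_returns_base(self, params):
        terr, roads = self.build(CLASS_PRIMARY)
        assert road_adjusted_annual_survival(0.9, terr, roads, False, params) == 0.9
        terr2, roads2 = self.build(None)
        assert road_adjusted_annual_survival(0.9, terr2, roads2, True, params) == 0.9

    def test_counterless_territory_recomputed_from_layer(self, params):
        # a Territory built by hand (no counter maintenance) still works
        from tigersim.territory import Territory
        grid = np.zeros((5, 5), dtype=np.uint8)
        grid[2, 2] = CLASS_PRIMARY
        roads = RoadLayer(class_grid=grid)
        terr = Territory(owner_id=1, origin=(2, 2), cells={(2, 2), (2, 3)})
        assert road_adjusted_annual_survival(0.9, terr, roads, True, params) == 0.297


class TestMonthlySurvival:
    @pytest.mark.parametrize("annual,expected", [
        (1.0, 1.0),
        (0.9, 0.9 ** (1 / 12)),
        (0.297, 0.297 ** (1 / 12)),
    ])
    def test_twelfth_root(self, annual, expected):
        assert monthly_survival(annual) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected_zero_allowed(self):
        with pytest.raises(ValueError):
            monthly_survival(-0.1)
        assert monthly_survival(0.0) == 0.0

    def test_hazard_limits(self):
        assert conception_hazard(1.0) == 1.0
        assert conception_hazard(0.0) == 0.0
        assert 0 < conception_hazard(0.9) < 1


class TestApplyMortality:
    def big_female_population(self, n, road_class=None):
        """n one-cell territories on an n-cell strip; prey rich enough that
        no one is ever below the minimum."""
        shape = (1, n)
        grid = np.zeros(shape, dtype=np.uint8)
        if road_class is not None:
            grid[:] = road_class
        prey = PreyGrid(production=np.full(shape, 1000.0),
                        mask=np.ones(shape, dtype=bool))
        roads = RoadLayer(class_grid=grid)
        tmap = make_tmap(prey, roads)
        tigers = {}
        for i in range(n):
            f = Tiger(i + 1, "F", 60, natal_center=(0, i))
            tmap.settle(f.id, (0, i))
            f.territory_id = f.id
            tigers[f.id] = f
        return tigers, tmap, roads

    def test_realized_annual_survival_no_roads(self, params):
        rng = np.random.default_rng(11)
        tigers, tmap, roads = self.big_female_population(10_000)
        for step in range(12):
            events = apply_mortality(tigers, tmap, roads, set(), params, rng, step)
            for e in events:
                del tigers[e.tiger_id]
        assert len(tigers) / 10_000 == pytest.approx(0.9, abs=0.01)

    def test_realized_annual_survival_primary_road(self, params):
        rng = np.random.default_rng(12)
        tigers, tmap, roads = self.big_female_population(
            10_000, road_class=CLASS_PRIMARY)
        for step in range(12):
            events = apply_mortality(tigers, tmap, roads, {"mortality"},
                                     params, rng, step)
            for e in events:
                assert e.road_intersect == "primary"
                del tigers[e.tiger_id]
        assert len(tigers) / 10_000 == pytest.approx(0.297, abs=0.015)

    def test_mother_death_kills_dependents_same_step(self, params):
        tigers, tmap, roads = self.big_female_population(1)
        mother = tigers[1]
        for i in range(3):
            cub = Tiger(10 + i, "F", 4, mother_id=1, natal_center=(0, 0))
            tigers[cub.id] = cub
        doomed = Params.from_dict({**params.to_dict(),
                                   "survival_breeding_female": 0.0})
        rng = np.random.default_rng(0)
        events = apply_mortality(tigers, tmap, roads, set(), doomed, rng, 1)
        assert len(events) == 4
        causes = sorted(e.cause for e in events)
        assert causes == ["background", "orphaned", "orphaned", "orphaned"]
        assert all(not t.alive for t in tigers.values())

    def test_all_zero_survival_extinguishes_in_one_step(self, params):
        tigers, tmap, roads = self.big_female_population(50)
        for i in range(50):
            cub = Tiger(1000 + i, "M", 3, mother_id=i + 1, natal_center=(0, i))
            tigers[cub.id] = cub
        doomed = Params.from_dict({**params.to_dict(), **{
            k: 0.0 for k in ("survival_breeding_male", "survival_breeding_female",
                             "survival_dispersal_male", "survival_transient_male",
                             "survival_transient_female", "survival_juvenile",
                             "survival_cub")}})
        rng = np.random.default_rng(1)
        events = apply_mortality(tigers, tmap, roads, set(), doomed, rng, 1)
        assert len(events) == 100
        assert all(not t.alive for t in tigers.values())


class TestStarvation:
    def test_never_starves_above_minimum(self, params):
        f = Tiger(1, "F", 60)
        for _ in range(24):
            assert not check_starvation(f, 80.0, params)
        assert f.months_below_min == 0

    def test_dies_after_three_consecutive_months(self, params):
        f = Tiger(1, "F", 60)
        assert not check_starvation(f, 50.0, params)
        assert not check_starvation(f, 50.0, params)
        assert check_starvation(f, 50.0, params)

    def test_counter_resets_on_recovery(self, params):
        f = Tiger(1, "F", 60)
        check_starvation(f, 50.0, params)
        check_starvation(f, 50.0, params)
        assert not check_starvation(f, 80.0, params)
        assert f.months_below_min == 0
        assert not check_starvation(f, 50.0, params)

    def test_grace_period_protects_fresh_settlers(self, params):
        # via apply_mortality: a below-minimum female within the grace
        # survives; past the grace she starves
        prey = PreyGrid(production=np.full((5, 5), 1.0),
                        mask=np.ones((5, 5), dtype=bool))
        roads = RoadLayer(class_grid=np.zeros((5, 5), dtype=np.uint8))
        tmap = make_tmap(prey, roads)
        f = settled_female(tmap, fid=1, origin=(2, 2))
        tigers = {1: f}
        safe = Params.from_dict({**params.to_dict(),
                                 "survival_breeding_female": 1.0})
        rng = np.random.default_rng(2)
        deaths = []
        for step in range(1, 10):
            deaths += apply_mortality(tigers, tmap, roads, set(), safe, rng, step)
            if deaths:
                break
        assert deaths[0].cause == "starvation"
        assert deaths[0].step == params.starvation_grace_months + 1


class TestReproduce:
    def eligible_female(self, age=60, prey_value=1000.0):
        prey = PreyGrid(production=np.full((5, 5), prey_value),
                        mask=np.ones((5, 5), dtype=bool))
        tmap = make_tmap(prey)
        f = settled_female(tmap, fid=1, origin=(2, 2), age=age)
        m = Tiger(2, "M", 72, natal_center=(2, 2))
        m.female_ids = [1]
        f.associated_male_id = 2
        return f, m, tmap

    def test_certain_conception_at_p1(self, params, rng):
        f, m, tmap = self.eligible_female(age=60)
        reproduce({1: f, 2: m}, tmap, params, rng, 1, lambda *a: None)
        assert f.gestation_remaining in (3, 4)

    def test_no_conception_with_living_dependents(self, params, rng):
        f, m, tmap = self.eligible_female()
        cub = Tiger(3, "F", 5, mother_id=1, natal_center=(2, 2))
        reproduce({1: f, 2: m, 3: cub}, tmap, params, rng, 1, lambda *a: None)
        assert f.gestation_remaining == 0

    def test_no_conception_without_male(self, params, rng):
        f, _, tmap = self.eligible_female()
        f.associated_male_id = None
        reproduce({1: f}, tmap, params, rng, 1, lambda *a: None)
        assert f.gestation_remaining == 0

    def test_birth_at_gestation_zero(self, params, rng):
        f, m, tmap = self.eligible_female()
        f.gestation_remaining = 1
        born = []
        reproduce({1: f, 2: m}, tmap, params, rng, 1,
                  lambda mother, size, sexes: born.append((mother.id, size)))
        assert born and born[0][0] == 1
        assert 2 <= born[0][1] <= 5

    def test_gestation_split_is_even(self, params):
        rng = np.random.default_rng(21)
        draws = []
        for _ in range(10_000):
            f, m, tmap = self.eligible_female()
            reproduce({1: f, 2: m}, tmap, params, rng, 1, lambda *a: None)
            draws.append(f.gestation_remaining)
        assert np.mean([d == 3 for d in draws]) == pytest.approx(0.5, abs=0.02)


class TestChallenges:
    def arena(self, challenger_age=72, incumbent_age=72, dependents=()):
        prey = PreyGrid(production=np.full((10, 10), 1000.0),
                        mask=np.ones((10, 10), dtype=bool))
        tmap = make_tmap(prey)
        f = settled_female(tmap, fid=1, origin=(5, 5))
        inc = Tiger(2, "M", incumbent_age, natal_center=(5, 5))
        inc.location = (5, 5)
        inc.female_ids = [1]
        f.associated_male_id = 2
        ch = Tiger(3, "M", challenger_age, natal_center=(5, 6))
        ch.location = (5, 6)
        tigers = {1: f, 2: inc, 3: ch}
        for i, stage_age in enumerate(dependents):
            d = Tiger(10 + i, "F", stage_age, mother_id=1, natal_center=(5, 5))
            tigers[d.id] = d
        return tigers, tmap, f, inc, ch

    def test_equal_age_win_probability_half(self, params):
        rng = np.random.default_rng(31)
        wins = 0
        n = 10_000
        for _ in range(n):
            tigers, tmap, f, inc, ch = self.arena()
            out = resolve_challenge(ch, inc, tigers, tmap, params, rng, 1)
            wins += out.challenger_won
        assert wins / n == pytest.approx(0.5, abs=0.02)

    def test_loss_and_win_death_frequencies(self, params):
        rng = np.random.default_rng(32)
        ch_deaths = ch_losses = inc_deaths = inc_losses = 0
        for _ in range(20_000):
            tigers, tmap, f, inc, ch = self.arena()
            out = resolve_challenge(ch, inc, tigers, tmap, params, rng, 1)
            if out.challenger_won:
                inc_losses += 1
                inc_deaths += not inc.alive
            else:
                ch_losses += 1
                ch_deaths += not ch.alive
        assert ch_deaths / ch_losses == pytest.approx(0.25, abs=0.02)
        assert inc_deaths / inc_losses == pytest.approx(0.6, abs=0.02)

    def test_infanticide_frequencies(self, params):
        rng = np.random.default_rng(33)
        cub_dead = cub_n = juv_dead = juv_n = 0
        while cub_n < 10_000:
            tigers, tmap, f, inc, ch = self.arena(dependents=(5, 18))
            out = resolve_challenge(ch, inc, tigers, tmap, params, rng, 1)
            if out.challenger_won:
                cub_n += 1
                juv_n += 1
                cub_dead += not tigers[10].alive
                juv_dead += not tigers[11].alive
        assert cub_dead / cub_n == pytest.approx(0.79, abs=0.02)
        assert juv_dead / juv_n == pytest.approx(0.24, abs=0.02)

    def test_females_transfer_on_win(self, params):
        rng = np.random.default_rng(34)
        for _ in range(50):
            tigers, tmap, f, inc, ch = self.arena()
            out = resolve_challenge(ch, inc, tigers, tmap, params, rng, 1)
            if out.challenger_won:
                assert f.associated_male_id == 3
                assert ch.female_ids == [1]
                assert inc.female_ids == []
            else:
                assert f.associated_male_id == 2

    def test_prime_age_weight_shape(self):
        assert challenge_weight(36) == 1.0
        assert challenge_weight(60) == 2.0
        assert challenge_weight(84) == 2.0
        assert challenge_weight(108) == 2.0
        assert challenge_weight(144) == 1.0
        assert challenge_weight(300) == 1.0
        assert 1.0 < challenge_weight(48) < 2.0
        assert 1.0 < challenge_weight(126) < 2.0
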