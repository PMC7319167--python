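"""Yearly scheduler: resource economy, demography, reproduction, groups."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from tribesim import WorldConfig, allocate_hauls, init_population, run_simulation
from tribesim.config import ConfigError
from tribesim.genetics import LocusSpec
from tribesim.memes import Meme
from tribesim.population import (
    Group,
    Individual,
    WorldState,
    cohort_lifespans,
    death_step,
    expected_lifespan,
    hunting_step,
    life_support_step,
    migration_step,
    reproduction_step,
    run_year,
    sharing_step,
    split_step,
    useless_step,
)

from conftest import disable_invention


def make_individual(config, ind_id=0, age=10, resources=10.0, mc=0.0):
    geno = np.array([[mc, mc], [1.0, 1.0], [0.0, 0.0]])
    return Individual(ind_id, age, resources, geno, config)


def make_state(config, group_sizes, resources=10.0, age=10):
    groups = []
    next_id = 0
    for gi, size in enumerate(group_sizes):
        members = [make_individual(config, next_id + k, age=age,
                                   resources=resources) for k in range(size)]
        next_id += size
        groups.append(Group(gi, members))
    return WorldState(groups, np.random.default_rng(0),
                      next_individual_id=next_id)


class TestInitPopulation:
    @pytest.mark.parametrize("n0, g_max, n_groups", [
        (250, 800, 1),
        (250, 40, 7),   # ceiling division
        (80, 40, 2),
    ])
    def test_group_count(self, n0, g_max, n_groups, rng):
        cfg = WorldConfig(initial_population=n0, G_max=g_max)
        state = init_population(cfg, rng)
        assert len(state.groups) == n_groups
        assert state.population == n0

    def test_founders_have_zero_memory_capacity(self, rng):
        state = init_population(WorldConfig(), rng)
        assert all(ind.memory.capacity == 0.0 for ind in state.individuals())

    def test_too_small_population_rejected(self):
        with pytest.raises(ConfigError):
            WorldConfig(initial_population=1)


class TestLifeSupport:
    def test_full_payment(self, default_config):
        state = make_state(default_config, [1], resources=10.0)
        life_support_step(state, default_config)
        ind = state.individuals()[0]
        assert ind.resources == 7.0 and not ind.hungry_last_year

    def test_partial_payment_marks_hungry(self, default_config):
        state = make_state(default_config, [1], resources=2.0)
        life_support_step(state, default_config)
        ind = state.individuals()[0]
        assert ind.resources == 0.0 and ind.hungry_last_year
        assert not ind.starving  # first hungry year is not lethal

    def test_two_hungry_years_flag_death(self, default_config):
        state = make_state(default_config, [2], resources=1.0)
        life_support_step(state, default_config)
        life_support_step(state, default_config)
        assert all(ind.starving for ind in state.individuals())
        death_step(state, default_config)
        assert state.population == 0


class TestHuntingAllocation:
    @pytest.mark.parametrize("efforts, r, expected", [
        ((2000.0, 4000.0), 3000.0, (1000.0, 2000.0)),  # proportional contest
        ((500.0, 800.0), 3000.0, (500.0, 800.0)),      # supply not limiting
        ((0.0,), 3000.0, (0.0,)),
    ])
    def test_quoted_allocations(self, efforts, r, expected):
        assert allocate_hauls(efforts, r) == pytest.approx(list(expected))

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        # independently coded allocator: elementwise min of identity and
        # proportional share, switching on total effort
        for _ in range(1000):
            k = int(rng.integers(1, 8))
            efforts = rng.uniform(0.0, 2000.0, size=k)
            r = float(rng.uniform(100.0, 5000.0))
            got = np.array(allocate_hauls(efforts, r))
            total = efforts.sum()
            want = efforts if total <= r else efforts * (r / total)
            np.testing.assert_allclose(got, want, rtol=1e-12)
            assert got.sum() <= max(r, total if total <= r else r) + 1e-9

    def test_hunters_pay_cost_and_poor_stay_home(self, default_config):
        state = make_state(default_config, [2], resources=10.0)
        poor = state.groups[0].members[0]
        poor.resources = 1.0  # below the hunting cost
        hauls = hunting_step(state, default_config)
        assert poor.resources == 1.0
        assert state.groups[0].members[1].resources == 8.0
        assert hauls == pytest.approx([10.0])  # one hunter with HE = 10


class TestSharing:
    def test_equal_trick_efficiency_splits_equally(self, default_config):
        state = make_state(default_config, [3], resources=0.0)
        sharing_step(state.groups[0], 90.0)
        assert [i.resources for i in state.individuals()] == pytest.approx(
            [30.0, 30.0, 30.0])

    def test_tricksters_claim_weighted_share(self, default_config):
        state = make_state(default_config, [2], resources=0.0)
        trickster = state.groups[0].members[0]
        trickster.memory = _unbounded_memory(Meme(0, "TrE", 1.0, 1.0))
        trickster.invalidate_traits()
        sharing_step(state.groups[0], 100.0)
        # weights 1 + TrE: 2 vs 1
        assert trickster.resources == pytest.approx(200.0 / 3.0)
        assert state.groups[0].members[1].resources == pytest.approx(100.0 / 3.0)

    def test_shares_sum_exactly_to_haul(self, default_config, rng):
        state = make_state(default_config, [7], resources=0.0)
        haul = 123.456
        sharing_step(state.groups[0], haul)
        assert sum(i.resources for i in state.individuals()) == pytest.approx(
            haul, abs=1e-9)

    def test_single_member_takes_all(self, default_config):
        state = make_state(default_config, [1], resources=0.0)
        sharing_step(state.groups[0], 42.0)
        assert state.individuals()[0].resources == 42.0


def _unbounded_memory(*memes):
    from tribesim.memes import Memory
    mem = Memory(1e9)
    for m in memes:
        mem.add(m)
    return mem


class TestUselessActions:
    def test_empirical_rate_matches_combined_propensity(self, default_config):
        # memes of efficiency 0.2 and 0.3 combine to acting rate 0.44
        state = make_state(default_config, [1], resources=10.0)
        ind = state.individuals()[0]
        ind.memory = _unbounded_memory(Meme(0, "Useless", 1.0, 0.2),
                                       Meme(1, "Useless", 1.0, 0.3))
        ind.invalidate_traits()
        n, acted = 100_000, 0
        for _ in range(n):
            ind.resources = 10.0
            useless_step(state, default_config)
            if ind.resources < 10.0:
                acted += 1
        half = 2.576 * math.sqrt(0.44 * 0.56 / n)
        assert abs(acted / n - 0.44) < half * 1.5

    def test_broke_individual_never_acts(self, default_config):
        state = make_state(default_config, [1], resources=0.0)
        ind = state.individuals()[0]
        ind.memory = _unbounded_memory(Meme(0, "Useless", 1.0, 1.0))
        ind.invalidate_traits()
        for _ in range(100):
            useless_step(state, default_config)
        assert ind.resources == 0.0


class TestDeath:
    def test_hazard_is_age_proportional_and_capped(self, default_config):
        state = make_state(default_config, [3, 3], age=0)
        death_step(state, default_config)
        assert state.population == 6  # age 0: hazard 0
        state = make_state(default_config, [3, 3], age=500)
        death_step(state, default_config)
        assert state.population == 0  # hazard capped at 1

    def test_lone_survivor_of_a_group_dies(self, default_config):
        state = make_state(default_config, [1, 5], age=0)
        death_step(state, default_config)
        assert len(state.groups) == 1 and state.population == 5

    def test_cohort_mean_matches_analytic_survival_sum(self, rng):
        lifespans = cohort_lifespans(100_000, 0.002, rng)
        expected = expected_lifespan(0.002)
        assert expected == pytest.approx(27.7, abs=0.05)
        assert np.mean(lifespans) == pytest.approx(expected, rel=0.01)


class TestReproduction:
    @staticmethod
    def _no_mutation_config():
        loci = {
            "MC": LocusSpec("MC", 0.0),
            "LE": LocusSpec("LE", 1.0, upper_bound=1.0),
            "TE": LocusSpec("TE", 0.0, upper_bound=1.0),
        }
        return WorldConfig(locus_specs=loci)

    def _adult_pair(self, config, r1, r2):
        state = make_state(config, [2], age=10)
        a, b = state.individuals()
        a.resources, b.resources = r1, r2
        return state, a, b

    def test_transfer_arithmetic(self):
        # pooled 100, child brain 20 -> cost 40; child 16 + 24; parents 18 each
        cfg = self._no_mutation_config()
        state, a, b = self._adult_pair(cfg, 60.0, 40.0)
        reproduction_step(state, cfg)
        assert state.population == 3
        child = [i for i in state.individuals() if i.age == 0][0]
        assert child.resources == pytest.approx(40.0)
        assert a.resources == pytest.approx(18.0)
        assert b.resources == pytest.approx(18.0)
        assert len(child.memory) == 0

    def test_unaffordable_child_fails_without_resource_movement(
            self, default_config):
        state, a, b = self._adult_pair(default_config, 10.0, 20.0)
        reproduction_step(state, default_config)
        assert state.population == 2
        assert (a.resources, b.resources) == (10.0, 20.0)

    def test_age_six_exactly_not_eligible(self, default_config):
        state = make_state(default_config, [2], age=6, resources=100.0)
        reproduction_step(state, default_config)
        assert state.population == 2

    def test_odd_group_leaves_one_unpaired(self, default_config):
        state = make_state(default_config, [5], age=10, resources=100.0)
        reproduction_step(state, default_config)
        assert state.population == 5 + 2  # two pairs reproduce


class TestSplitting:
    @pytest.mark.parametrize("size, g_max, expected_sizes", [
        (40, 40, [40]),
        (41, 40, [21, 20]),
        (80, 40, [40, 40]),
    ])
    def test_split_rule(self, size, g_max, expected_sizes):
        cfg = WorldConfig(G_max=g_max)
        state = make_state(cfg, [size])
        split_step(state, cfg)
        assert sorted((len(g) for g in state.groups), reverse=True) == \
            sorted(expected_sizes, reverse=True)


class TestMigration:
    def test_no_migration_at_zero_rate(self):
        cfg = WorldConfig(migration_rate=0.0)
        state = make_state(cfg, [5, 5])
        migration_step(state, cfg)
        assert [len(g) for g in state.groups] == [5, 5]

    def test_single_group_is_a_noop(self):
        cfg = WorldConfig(migration_rate=1.0)
        state = make_state(cfg, [5])
        migration_step(state, cfg)
        assert len(state.groups) == 1 and state.population == 5

    def test_rate_matches_binomial_oracle(self):
        cfg = WorldConfig(migration_rate=0.001)
        n_trials = 100_000
        moved = 0
        state = make_state(cfg, [500, 500])
        for _ in range(n_trials // 1000):
            before = {id(ind): gi for gi, g in enumerate(state.groups)
                      for ind in g.members}
            migration_step(state, cfg)
            after = {id(ind): gi for gi, g in enumerate(state.groups)
                     for ind in g.members}
            moved += sum(before[k] != after[k] for k in before)
        p = 0.001
        half = 2.576 * math.sqrt(p * (1 - p) / n_trials)
        assert abs(moved / n_trials - p) < half * 1.5


class TestYearLoop:
    def test_null_dynamics_without_mutation_or_invention(self):
        loci = {
            "MC": LocusSpec("MC", 0.0),
            "LE": LocusSpec("LE", 1.0, upper_bound=1.0),
            "TE": LocusSpec("TE", 0.0, upper_bound=1.0),
        }
        cfg = disable_invention(WorldConfig(
            locus_specs=loci, migration_rate=0.0, years=100, seed=3,
            initial_population=100))
        df = run_simulation(cfg)
        assert (df.cultural_richness == 0).all()
        assert (df.mean_genotypic_mc == 0).all()
        assert (df.mean_brain_volume == 20.0).all()

    def test_same_seed_reproduces_identical_trajectory(self):
        cfg = WorldConfig(years=60, seed=42, initial_population=100)
        df1 = run_simulation(cfg)
        df2 = run_simulation(cfg)
        pd.testing.assert_frame_equal(df1, df2)

    def test_population_bounded_by_resource_balance(self):
        # long-run population cannot exceed R_env / life-support cost,
        # plus one birth cohort
        cfg = WorldConfig(years=300, seed=5)
        df = run_simulation(cfg)
        bound = cfg.R_env / cfg.life_support_cost
        assert df.population.iloc[100:].max() <= bound + df.births.max()
        assert 200 <= df.population.iloc[-1] <= 1000

    def test_memory_and_resource_invariants_hold_every_year(self):
        # instrumented short culture-rich run: capacity respected, hauls
        # never exceed the supply, shares conserve the haul
        cfg = WorldConfig(years=0, seed=9, initial_population=80, G_max=40)
        params = {c: dataclasses.replace(p, invention_rate=0.05)
                  for c, p in cfg.meme_params.items()}
        cfg = cfg.replace(meme_params=params)
        rng = np.random.default_rng(cfg.seed)
        state = init_population(cfg, rng)
        from tribesim.population import (forgetting_step, invention_step,
                                         learning_step, teaching_step)
        for _ in range(120):
            life_support_step(state, cfg)
            invention_step(state, cfg)
            forgetting_step(state, cfg)
            teaching_step(state, cfg)
            pre = {g.id: sum(i.resources for i in g.members)
                   for g in state.groups}
            hauls = hunting_step(state, cfg)
            assert sum(hauls) <= cfg.R_env + 1e-9
            for g, haul in zip(state.groups, hauls):
                mid = sum(i.resources for i in g.members)
                sharing_step(g, haul)
                post = sum(i.resources for i in g.members)
                assert post - mid == pytest.approx(haul, abs=1e-9)
            useless_step(state, cfg)
            learning_step(state, cfg)
            death_step(state, cfg)
            reproduction_step(state, cfg)
            split_step(state, cfg)
            migration_step(state, cfg)
            for ind in state.individuals():
                ind.age += 1
                assert ind.memory.used <= ind.memory.capacity + 1e-9
                ids = ind.memory.meme_ids()
                assert len(ids) == len(set(ids))
            assert all(len(g) <= cfg.G_max for g in state.groups)
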