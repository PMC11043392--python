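"""Demographic operators: worked examples and structural invariants."""

import math

import numpy as np
import pytest
from scipy.stats import truncnorm

from conftest import manual_pop, tiny_config
from kinsim import demography
from kinsim.config import SimulationConfig
from kinsim.demography import (
    FissionOutcome,
    apply_violence,
    assign_offspring,
    check_and_execute_fissions,
    draw_split_proportion,
    father_group_probabilities,
    form_mating_pairs,
    form_polygynous_pairs,
    lineal_partition,
    migrate_individuals,
    post_fission_migrate,
    remove_extinct_groups,
    reproduce,
    violence_rates,
)
from kinsim.population import FEMALE, MALE, Pedigree, initialize_population


class TestFatherGroupProbabilities:
    def test_small_fitness_edge(self):
        # two equal groups, fitnesses 0.1 and 0.0
        p = father_group_probabilities(np.array([10, 10]), np.array([0.1, 0.0]))
        expected = math.exp(0.1) / (math.exp(0.1) + 1.0)
        assert p[0] == pytest.approx(expected, abs=1e-5)
        assert p[0] == pytest.approx(0.52498, abs=1e-4)
        assert p.sum() == pytest.approx(1.0)

    def test_equal_groups_are_symmetric(self):
        p = father_group_probabilities(np.array([50, 50]), np.array([0.01, 0.01]))
        assert p.tolist() == pytest.approx([0.5, 0.5])

    def test_size_weighting(self):
        p = father_group_probabilities(np.array([30, 10]), np.array([0.0, 0.0]))
        assert p.tolist() == pytest.approx([0.75, 0.25])

    def test_no_males_raises(self):
        with pytest.raises(ValueError):
            father_group_probabilities(np.array([0, 0]), np.array([0.0, 0.0]))


class TestViolenceRates:
    def test_two_group_worked_example(self):
        # N = (400, 100), e = 0.15: rho = 0.0125, E[D] = (25, 50)
        rho, expected = violence_rates({"a": 400, "b": 100}, 0.15)
        assert rho == pytest.approx(0.0125)
        assert expected["a"] == pytest.approx(25.0)
        assert expected["b"] == pytest.approx(50.0)

    def test_symmetric_groups_share_kills_equally(self):
        rho, expected = violence_rates({0: 100, 1: 100}, 0.15)
        assert expected[0] == pytest.approx(15.0)
        assert expected[1] == pytest.approx(15.0)

    def test_expectations_sum_to_global_rate(self):
        counts = {0: 37, 1: 121, 2: 4, 3: 260}
        for e in (0.05, 0.15, 0.4):
            _, expected = violence_rates(counts, e)
            assert sum(expected.values()) == pytest.approx(e * sum(counts.values()))

    def test_smaller_group_faces_higher_per_capita_risk(self):
        _, expected = violence_rates({0: 400, 1: 100}, 0.15)
        assert expected[1] / 100 > expected[0] / 400

    def test_single_group_has_no_rivals(self):
        rho, expected = violence_rates({0: 200}, 0.15)
        assert rho == 0.0
        assert expected[0] == 0.0

    def test_village_arena_respects_local_quotas(self):
        counts = {0: 60, 1: 40, 2: 80}
        villages = {0: 0, 1: 0, 2: 1}  # group 2 monopolises village 1
        _, expected = violence_rates(counts, 0.15, villages)
        assert expected[2] == 0.0
        assert expected[0] + expected[1] == pytest.approx(0.15 * 100)


class TestApplyViolence:
    def test_realized_kills_match_global_rate(self):
        rng = np.random.default_rng(77)
        totals = []
        for _ in range(200):
            pop = manual_pop([(0, 200, 200), (1, 100, 100), (2, 100, 100)])
            draw = apply_violence(pop, 0.15, rng)
            assert draw.realized_total == 800 - pop.size
            totals.append(draw.realized_total)
        # E = 0.15 * 400 males = 60; MC standard error ~ 0.55
        assert np.mean(totals) == pytest.approx(60.0, abs=2.0)

    def test_kills_truncated_at_group_male_count(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            pop = manual_pop([(0, 2, 50), (1, 300, 300), (2, 50, 50)])
            draw = apply_violence(pop, 0.3, rng)
            assert draw.kills.get(0, 0) <= 2

    def test_single_group_population_falls_back_to_uniform(self):
        rng = np.random.default_rng(1)
        pop = manual_pop([(0, 100, 100)])
        draw = apply_violence(pop, 0.15, rng)
        assert draw.realized_total == 15
        assert any(e.get("fallback") for e in pop.events if e["type"] == "kills")

    def test_village_arena_monopolies_see_no_kills(self):
        rng = np.random.default_rng(2)
        pop = manual_pop([(0, 100, 100), (1, 80, 80), (2, 60, 60)])
        draw = apply_violence(pop, 0.15, rng, arena="village")
        assert draw.realized_total == 0
        assert pop.size == 480

    def test_only_males_are_killed(self):
        rng = np.random.default_rng(3)
        pop = manual_pop([(0, 100, 100), (1, 100, 100)])
        apply_violence(pop, 0.15, rng)
        assert int((pop.sex == FEMALE).sum()) == 200


class TestMating:
    def test_exogamy_avoids_same_group_couples(self):
        rng = np.random.default_rng(11)
        male_groups = np.array([0] * 5 + [1] * 5)
        female_groups = np.array([0] * 5 + [1] * 5)
        pool = form_mating_pairs(male_groups, female_groups, True, rng)
        assert pool.n_pairs == 10
        assert (male_groups[pool.male_sel] != female_groups[pool.female_sel]).all()
        assert len(set(pool.female_sel.tolist())) == 10

    def test_pair_count_is_min_of_sexes(self):
        rng = np.random.default_rng(12)
        pool = form_mating_pairs(np.zeros(7, int), np.zeros(4, int), False, rng)
        assert pool.n_pairs == 4
        assert pool.n_single_males == 3
        assert pool.n_single_females == 0

    def test_single_group_village_falls_back_to_endogamy(self):
        rng = np.random.default_rng(13)
        pool = form_mating_pairs(np.zeros(6, int), np.zeros(6, int), True, rng)
        assert pool.n_pairs == 6

    def test_polygynous_pairs_marry_every_female(self):
        rng = np.random.default_rng(14)
        pool = form_polygynous_pairs(5, 20, 0.5, rng)
        assert pool.n_pairs == 20
        assert pool.female_sel.tolist() == list(range(20))
        assert set(pool.male_sel.tolist()) <= set(range(5))

    def test_polygyny_produces_more_sires_skew_than_monogamy(self):
        rng = np.random.default_rng(15)
        # repeated draws: the most-married male's share under geometric
        # weights exceeds the uniform 1/n share on average
        shares = []
        for _ in range(200):
            pool = form_polygynous_pairs(20, 100, 0.5, rng)
            shares.append(np.bincount(pool.male_sel, minlength=20).max() / 100)
        assert np.mean(shares) > 1.5 / 20


class TestAssignOffspring:
    def test_draws_follow_fitness_weighted_group_probabilities(self):
        rng = np.random.default_rng(21)
        pair_groups = np.array([0, 0, 1])
        chosen = assign_offspring(
            demography.MatingPool(np.arange(3), np.arange(3), 0, 0),
            pair_groups,
            {0: 2, 1: 5},
            {0: 0.0, 1: 0.0},
            20_000,
            rng,
        )
        frac_g1 = (pair_groups[chosen] == 1).mean()
        assert frac_g1 == pytest.approx(5 / 7, abs=0.01)

    def test_all_children_map_to_existing_couples(self):
        rng = np.random.default_rng(22)
        pair_groups = np.array([0, 1, 1, 2])
        chosen = assign_offspring(
            demography.MatingPool(np.arange(4), np.arange(4), 0, 0),
            pair_groups,
            {0: 10, 1: 10, 2: 10},
            {0: 0.01, 1: 0.01, 2: 0.01},
            500,
            rng,
        )
        assert chosen.min() >= 0 and chosen.max() < 4
        assert len(chosen) == 500


class TestReproduce:
    def test_odd_target_yields_extra_male(self):
        # 303 children split 152 males / 151 females (alternating, male first)
        cfg = SimulationConfig(
            n_total=12, n_villages=1, village_init_size=12, group_init_size=4
        )
        rng = np.random.default_rng(31)
        pop = initialize_population(cfg, rng)
        reproduce(pop, cfg, 303, True, rng)
        assert pop.size == 303
        assert int((pop.sex == MALE).sum()) == 152
        assert int((pop.sex == FEMALE).sum()) == 151
        assert pop.sex[0] == MALE

    def test_missing_sex_raises(self):
        cfg = tiny_config()
        rng = np.random.default_rng(32)
        pop = manual_pop([(0, 5, 0), (1, 5, 5), (2, 5, 5)])
        with pytest.raises(RuntimeError, match="lacks one sex"):
            reproduce(pop, cfg, 10, True, rng)


class TestSplitProportion:
    def test_matches_truncated_normal_moments(self):
        rng = np.random.default_rng(41)
        draws = np.array([draw_split_proportion(rng) for _ in range(5000)])
        assert draws.min() >= 0.0 and draws.max() <= 1.0
        sd = math.sqrt(0.5)
        dist = truncnorm((0 - 0.5) / sd, (1 - 0.5) / sd, loc=0.5, scale=sd)
        mean, var = dist.stats()
        assert draws.mean() == pytest.approx(float(mean), abs=0.02)
        assert draws.std() == pytest.approx(float(np.sqrt(var)), abs=0.02)


def _pedigree_with_clades(clade_sizes: list[int]) -> tuple[Pedigree, np.ndarray]:
    """Founding fathers plus ``clade_sizes[k]`` sons each; returns son ids."""
    ped = Pedigree()
    n_f = len(clade_sizes)
    founders = ped.append(np.full(n_f, -1), np.full(n_f, -1), 0)
    fathers = np.repeat(founders, clade_sizes)
    sons = ped.append(fathers, np.full(len(fathers), -1), 1)
    return ped, sons


class TestLinealPartition:
    def test_two_patrilines_split_exactly(self):
        ped, sons = _pedigree_with_clades([6, 4])
        rng = np.random.default_rng(51)
        mask = lineal_partition(sons, ped, 5, 0.6, rng)
        assert mask is not None
        assert mask[:6].all() and not mask[6:].any()

    def test_three_clades_greedy_packing(self):
        # clades {5, 3, 2}, target 0.5: the 5-clade alone is closest
        ped, sons = _pedigree_with_clades([5, 3, 2])
        rng = np.random.default_rng(52)
        mask = lineal_partition(sons, ped, 5, 0.5, rng)
        assert mask[:5].all() and not mask[5:].any()

    def test_star_genealogy_returns_none(self):
        ped, sons = _pedigree_with_clades([6])
        rng = np.random.default_rng(53)
        assert lineal_partition(sons, ped, 5, 0.5, rng) is None

    def test_split_uses_deepest_branching_level(self):
        # one founder, two sons, two grandsons each: the split must separate
        # the two grandparental sibships, never cut within one
        ped = Pedigree()
        (f,) = ped.append(np.array([-1]), np.array([-1]), 0)
        sons = ped.append(np.array([f, f]), np.array([-1, -1]), 1)
        grandsons = ped.append(
            np.array([sons[0], sons[0], sons[1], sons[1]]), np.full(4, -1), 2
        )
        rng = np.random.default_rng(54)
        mask = lineal_partition(grandsons, ped, 10, 0.5, rng)
        assert mask is not None
        assert mask[0] == mask[1]
        assert mask[2] == mask[3]
        assert mask[0] != mask[2]

    def test_both_sides_non_empty_even_at_extreme_targets(self):
        ped, sons = _pedigree_with_clades([6, 4])
        rng = np.random.default_rng(55)
        for target in (0.0, 1.0):
            mask = lineal_partition(sons, ped, 5, target, rng)
            assert 0 < mask.sum() < len(sons)


class TestFission:
    def test_threshold_is_strict(self):
        # 2 * 75 = 150 is not > N_max = 150: no fission
        cfg = tiny_config(fission_threshold=150, fission_type="random")
        rng = np.random.default_rng(61)
        pop = manual_pop([(0, 75, 75), (1, 5, 5), (2, 5, 5)])
        assert check_and_execute_fissions(pop, cfg, rng) == []
        pop = manual_pop([(0, 76, 76), (1, 5, 5), (2, 5, 5)])
        outcomes = check_and_execute_fissions(pop, cfg, rng)
        assert len(outcomes) == 1
        assert outcomes[0].parent == 0

    def test_cooldown_suppresses_recent_fissions(self):
        cfg = tiny_config(fission_threshold=150, fission_type="random")
        rng = np.random.default_rng(62)
        # generation 10, last fission at 8: 2 generations ago <= cooldown 3
        pop = manual_pop([(0, 90, 90), (1, 5, 5), (2, 5, 5)], last_fission=8)
        assert check_and_execute_fissions(pop, cfg, rng) == []
        pop = manual_pop([(0, 90, 90), (1, 5, 5), (2, 5, 5)], last_fission=6)
        assert len(check_and_execute_fissions(pop, cfg, rng)) == 1

    def test_children_partition_parent_and_balance_sexes(self):
        cfg = tiny_config(fission_threshold=150, fission_type="random", sigma=0.1)
        rng = np.random.default_rng(63)
        pop = manual_pop([(0, 80, 60), (1, 5, 5), (2, 5, 5)])
        (out,) = check_and_execute_fissions(pop, cfg, rng)
        a, b = out.children
        assert 0 not in pop.groups and a in pop.groups and b in pop.groups
        na = int((pop.group == a).sum())
        nb = int((pop.group == b).sum())
        assert na + nb == 140
        assert out.child_sizes == (na, nb)
        # females follow the realised male fraction
        males_a = int(((pop.group == a) & (pop.sex == MALE)).sum())
        females_a = na - males_a
        assert females_a == round(out.male_proportion * 60)
        # both children restart their fission clock at the current generation
        assert pop.groups[a].last_fission == pop.generation
        assert pop.groups[b].founding_generation == pop.generation

    def test_lineal_falls_back_to_random_on_star_genealogy(self):
        # a group whose males are all paternal brothers cannot be split
        # into clades: lineal fission degrades to a random split
        cfg = tiny_config(fission_threshold=20, fission_type="lineal")
        rng = np.random.default_rng(64)
        pop = manual_pop([(0, 0, 12), (1, 5, 5), (2, 5, 5)])
        (father,) = pop.pedigree.append(np.array([-1]), np.array([-1]), 0)
        sons = pop.pedigree.append(np.full(12, father), np.full(12, -1), 1)
        pop.ids = np.concatenate([pop.ids, sons])
        pop.sex = np.concatenate([pop.sex, np.ones(12, dtype=np.int8)])
        pop.village = np.concatenate([pop.village, np.zeros(12, dtype=np.int16)])
        pop.group = np.concatenate([pop.group, np.full(12, 0, dtype=np.int32)])
        (out,) = check_and_execute_fissions(pop, cfg, rng)
        assert out.fission_type == "random"
        assert any(e["type"] == "degenerate_lineal_fission" for e in pop.events)


class TestExtinctionAndGroupMigration:
    def test_empty_group_removed_and_logged(self):
        pop = manual_pop([(0, 10, 10), (0, 5, 5), (1, 5, 5), (2, 5, 5)])
        pop.group[pop.group == 1] = 0  # group 1 loses all members
        extinct = remove_extinct_groups(pop)
        assert extinct == [1]
        assert 1 not in pop.groups
        assert any(e["type"] == "extinction" for e in pop.events)

    def test_group_with_single_female_survives(self):
        pop = manual_pop([(0, 10, 10), (0, 0, 1), (1, 5, 5), (2, 5, 5)])
        assert remove_extinct_groups(pop) == []
        assert 1 in pop.groups

    def test_smaller_child_moves_to_smallest_other_village(self):
        rng = np.random.default_rng(71)
        pop = manual_pop(
            [(0, 30, 30), (0, 5, 5), (1, 20, 20), (2, 10, 10)], generation=10
        )
        out = FissionOutcome(
            parent=99,
            children=(0, 1),
            village=0,
            male_proportion=0.85,
            child_sizes=(60, 10),
            fission_type="random",
        )
        post_fission_migrate(pop, [out], rng)
        members = np.flatnonzero(pop.group == 1)
        assert (pop.village[members] == 2).all()  # village 2 is smallest
        assert pop.groups[1].village == 2
        # the larger child stays put
        assert (pop.village[pop.group == 0] == 0).all()

    def test_simultaneous_fissions_all_leave_their_sources(self):
        rng = np.random.default_rng(72)
        pop = manual_pop(
            [(0, 30, 30), (0, 5, 5), (1, 25, 25), (1, 4, 4), (2, 10, 10)],
            generation=10,
        )
        outs = [
            FissionOutcome(99, (0, 1), 0, 0.8, (60, 10), "random"),
            FissionOutcome(98, (2, 3), 1, 0.8, (50, 8), "random"),
        ]
        post_fission_migrate(pop, outs, rng)
        assert pop.groups[1].village != 0
        assert pop.groups[3].village != 1
        for gid in (1, 3):
            members = np.flatnonzero(pop.group == gid)
            assert (pop.village[members] == pop.groups[gid].village).all()


class TestMigration:
    def test_zero_rates_move_nobody(self, rng):
        pop = manual_pop([(0, 10, 10), (1, 10, 10), (2, 10, 10)])
        before = pop.village.copy()
        assert migrate_individuals(pop, 0.0, 0.0, rng) == 0
        assert (pop.village == before).all()

    def test_patrilocal_migration_moves_only_females(self):
        rng = np.random.default_rng(81)
        pop = manual_pop([(0, 10, 10), (1, 10, 10), (2, 10, 10)])
        male_villages = pop.village[pop.sex == MALE].copy()
        n = migrate_individuals(pop, 1.0, 0.0, rng)
        assert n == 30  # every female moved
        assert (pop.village[pop.sex == MALE] == male_villages).all()
        # migrants joined a group of their destination village
        for i in np.flatnonzero(pop.sex == FEMALE):
            assert pop.groups[int(pop.group[i])].village == pop.village[i]

    def test_migration_rate_expectation(self):
        rng = np.random.default_rng(82)
        moved = 0
        for _ in range(50):
            pop = manual_pop([(0, 50, 50), (1, 50, 50), (2, 50, 50)])
            moved += migrate_individuals(pop, 0.1, 0.0, rng)
        # E = 50 * 15 = 750, binomial sd ~ 26
        assert moved == pytest.approx(750, abs=100)
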