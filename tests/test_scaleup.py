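import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equiscale.errors import DomainError, UndefinedResultError
from equiscale.scaleup import (
    STRATEGIES,
    AllocationPlan,
    Scenario,
    allocate,
    compare_strategies,
    cost_per_life_saved,
    lives_for_budget,
    lives_saved,
    uncovered,
)

TOY_UNCOVERED = (200.0, 400.0, 500.0, 600.0, 800.0)
TOY_COVERED = (800.0, 600.0, 500.0, 400.0, 200.0)


class TestUncovered:
    def test_full_coverage_all_zero(self):
        assert uncovered([1.0] * 5, [1000.0] * 5).tolist() == [0.0] * 5

    def test_half_coverage(self):
        assert uncovered([0.5], [1000.0]).tolist() == [500.0]

    def test_toy(self, toy_pools):
        coverage, episodes = toy_pools
        pools = uncovered(coverage, episodes)
        np.testing.assert_allclose(pools, TOY_UNCOVERED)
        assert pools.sum() == 2500.0

    def test_bad_coverage(self):
        with pytest.raises(DomainError):
            uncovered([1.5], [100.0])


class TestAllocate:
    def test_equity_promoting_all_in_q5(self):
        plan = allocate("equity_promoting", 0.10, TOY_UNCOVERED)
        assert plan.newly_covered == (0.0, 0.0, 0.0, 0.0, 250.0)

    def test_inequity_promoting_spillover(self):
        plan = allocate("inequity_promoting", 0.10, TOY_UNCOVERED)
        assert plan.newly_covered == (200.0, 50.0, 0.0, 0.0, 0.0)

    def test_mainstream_proportional(self):
        plan = allocate("mainstream", 0.10, TOY_UNCOVERED, TOY_COVERED)
        np.testing.assert_allclose(
            plan.newly_covered, (80.0, 60.0, 50.0, 40.0, 20.0)
        )

    def test_equity_neutral_median_band(self):
        # band [0.45, 0.55] of 2500 = [1125, 1375]; cumulative pool edges are
        # 200/600/1100/1700/2500, so the band sits entirely inside Q4
        plan = allocate("equity_neutral", 0.10, TOY_UNCOVERED)
        np.testing.assert_allclose(
            plan.newly_covered, (0.0, 0.0, 0.0, 250.0, 0.0), atol=1e-9
        )
        # straddling case: step 0.4 -> band [750, 1750] over cumulative
        # edges 0/200/600/1100/1700/2500 spans Q4 fully plus parts of Q3/Q5
        wide = allocate("equity_neutral", 0.40, TOY_UNCOVERED)
        np.testing.assert_allclose(
            wide.newly_covered, (0.0, 0.0, 350.0, 600.0, 50.0), atol=1e-9
        )

    def test_mainstream_requires_covered(self):
        with pytest.raises(DomainError):
            allocate("mainstream", 0.10, TOY_UNCOVERED)

    def test_mainstream_zero_coverage_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="uniform"):
            plan = allocate("mainstream", 0.10, TOY_UNCOVERED, [0.0] * 5)
        np.testing.assert_allclose(plan.newly_covered, [50.0] * 5)

    @pytest.mark.parametrize("step", [0.0, -0.1, 1.5])
    def test_bad_step(self, step):
        with pytest.raises(DomainError):
            allocate("equity_promoting", step, TOY_UNCOVERED)

    def test_zero_uncovered(self):
        with pytest.raises(DomainError):
            allocate("equity_promoting", 0.1, [0.0] * 5)

    def test_unknown_strategy(self):
        with pytest.raises(DomainError):
            allocate("bogus", 0.1, TOY_UNCOVERED)

    @settings(max_examples=100)
    @given(
        pools=st.lists(st.floats(0, 1e5), min_size=5, max_size=5),
        covered=st.lists(st.floats(0, 1e5), min_size=5, max_size=5),
        step=st.floats(0.01, 1.0),
        strategy=st.sampled_from(STRATEGIES),
    )
    def test_conservation_and_caps(self, pools, covered, step, strategy):
        if sum(pools) <= 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = allocate(strategy, step, pools, covered)
        # conservation within one episode
        assert sum(plan.newly_covered) == pytest.approx(
            step * sum(pools), abs=1.0
        )
        # never allocate beyond a quintile's uncovered pool
        for n, pool in zip(plan.newly_covered, pools):
            assert n <= pool + 1e-6
        # coverage never exceeds 1 after allocation
        for n, pool, cov in zip(plan.newly_covered, pools, covered):
            total = pool + cov
            if total > 0:
                c_new = cov / total + n / total
                assert c_new <= 1.0 + 1e-9


def brute_force_lives(plan, coverage, episodes, deaths, e_adj):
    """Exact expectation over (covered, dies) outcome cells per quintile.

    Derives the untreated per-episode risk from the observed deaths at
    current coverage, then differences expected deaths at the two coverages.
    """
    total = 0.0
    for n, c0, eps, d_obs, e_pct in zip(
        plan.newly_covered, coverage, episodes, deaths, e_adj
    ):
        if eps == 0 or d_obs == 0:
            continue
        e = e_pct / 100.0
        risk = d_obs / (eps * (1 - c0 * e))
        c1 = min(1.0, c0 + n / eps)
        deaths_at = lambda c: eps * risk * (c * (1 - e) + (1 - c))
        total += deaths_at(c0) - deaths_at(c1)
    return total


class TestLivesSaved:
    def test_zero_allocation(self, toy_scenario):
        plan = AllocationPlan("equity_promoting", 0.0, (0.0,) * 5, (0.0,) * 5)
        assert lives_saved(
            plan, toy_scenario.coverage, toy_scenario.episodes,
            toy_scenario.pneumonia_deaths, toy_scenario.e_adj,
        ) == 0.0

    def test_single_quintile_full_coverage_perfect_effectiveness(self):
        plan = AllocationPlan("equity_promoting", 1.0,
                              (0, 0, 0, 0, 1000.0), (0, 0, 0, 0, 1.0))
        lives = lives_saved(
            plan, [0.0] * 5, [1000.0] * 5, [0, 0, 0, 0, 50.0], [100.0] * 5
        )
        assert lives == pytest.approx(50.0)

    def test_matches_brute_force_oracle(self, toy_scenario):
        pools = uncovered(toy_scenario.coverage, toy_scenario.episodes)
        covered = np.asarray(toy_scenario.episodes) - pools
        for strategy in STRATEGIES:
            plan = allocate(strategy, 0.25, pools, covered)
            got = lives_saved(
                plan, toy_scenario.coverage, toy_scenario.episodes,
                toy_scenario.pneumonia_deaths, toy_scenario.e_adj,
            )
            expected = brute_force_lives(
                plan, toy_scenario.coverage, toy_scenario.episodes,
                toy_scenario.pneumonia_deaths, toy_scenario.e_adj,
            )
            assert got == pytest.approx(expected, abs=1e-9)

    def test_equity_beats_mainstream_on_regressive_burden(self, toy_scenario):
        pools = uncovered(toy_scenario.coverage, toy_scenario.episodes)
        covered = np.asarray(toy_scenario.episodes) - pools
        args = (toy_scenario.coverage, toy_scenario.episodes,
                toy_scenario.pneumonia_deaths, toy_scenario.e_adj)
        equity = lives_saved(allocate("equity_promoting", 0.1, pools, covered), *args)
        mainstream = lives_saved(allocate("mainstream", 0.1, pools, covered), *args)
        assert equity >= mainstream


class TestCostPerLifeSaved:
    def test_single_quintile_arithmetic(self):
        scenario = Scenario(
            country="one", u5mr=(10.0,), coverage=(0.0,), episodes=(10_000.0,),
            pneumonia_deaths=(100.0,), e_adj=(100.0,), unit_cost=(2.0,),
        )
        plan = AllocationPlan("equity_promoting", 0.1, (1000.0,), (0.1,))
        cost, lives, cpls = cost_per_life_saved(plan, scenario)
        assert cost == pytest.approx(2000.0)
        assert lives == pytest.approx(10.0)
        assert cpls == pytest.approx(200.0)

    def test_scale_invariance_within_quintile(self):
        scenario = Scenario(
            country="one", u5mr=(10.0,), coverage=(0.0,), episodes=(10_000.0,),
            pneumonia_deaths=(100.0,), e_adj=(80.0,), unit_cost=(2.0,),
        )
        small = AllocationPlan("x", 0.05, (500.0,), (0.05,))
        double = AllocationPlan("x", 0.10, (1000.0,), (0.10,))
        cpls_small = cost_per_life_saved(small, scenario)[2]
        cpls_double = cost_per_life_saved(double, scenario)[2]
        assert cpls_small == pytest.approx(cpls_double)

    def test_zero_lives_is_error_not_infinity(self):
        scenario = Scenario(
            country="one", u5mr=(10.0,), coverage=(0.0,), episodes=(1000.0,),
            pneumonia_deaths=(0.0,), e_adj=(100.0,), unit_cost=(2.0,),
        )
        plan = AllocationPlan("x", 0.1, (100.0,), (0.1,))
        with pytest.raises(UndefinedResultError):
            cost_per_life_saved(plan, scenario)


class TestLivesForBudget:
    def test_single_quintile_one_life_budget(self):
        scenario = Scenario(
            country="one", u5mr=(10.0,), coverage=(0.0,), episodes=(10_000.0,),
            pneumonia_deaths=(100.0,), e_adj=(100.0,), unit_cost=(2.0,),
        )
        # CPLS = 2.0 / (100/10000) = 200 US$/life
        lives, capped = lives_for_budget(200.0, "equity_promoting", scenario)
        assert lives == pytest.approx(1.0, abs=1e-6)
        assert not capped

    def test_zero_budget_rejected(self, toy_scenario):
        with pytest.raises(DomainError):
            lives_for_budget(0.0, "equity_promoting", toy_scenario)

    def test_cap_flag_when_budget_covers_everyone(self, toy_scenario):
        lives, capped = lives_for_budget(1e12, "equity_promoting", toy_scenario)
        assert capped
        # cap equals covering every uncovered episode, any strategy
        lives2, _ = lives_for_budget(1e12, "mainstream", toy_scenario)
        assert lives == pytest.approx(lives2, rel=1e-6)

    def test_monotone_in_budget(self, toy_scenario):
        budgets = [100, 300, 1000, 3000, 10_000]
        for strategy in STRATEGIES:
            lives = [
                lives_for_budget(b, strategy, toy_scenario)[0] for b in budgets
            ]
            assert all(b >= a - 1e-9 for a, b in zip(lives, lives[1:]))


class TestCompareStrategies:
    def test_identical_quintiles_identical_cpls(self):
        scenario = Scenario(
            country="flat", u5mr=(100.0,) * 5, coverage=(0.4,) * 5,
            episodes=(1000.0,) * 5, pneumonia_deaths=(20.0,) * 5,
            e_adj=(80.0,) * 5, unit_cost=(1.5,) * 5,
        )
        results = compare_strategies(scenario, step=0.1, budget=1000.0)
        cpls = [r.cost_per_life_saved for r in results]
        assert all(c == pytest.approx(cpls[0]) for c in cpls)

    def test_mainstream_permutation_symmetry(self, toy_scenario):
        perm = [4, 2, 0, 3, 1]
        permuted = Scenario(
            country="toy",
            u5mr=tuple(toy_scenario.u5mr[i] for i in perm),
            coverage=tuple(toy_scenario.coverage[i] for i in perm),
            episodes=tuple(toy_scenario.episodes[i] for i in perm),
            pneumonia_deaths=tuple(toy_scenario.pneumonia_deaths[i] for i in perm),
            e_adj=tuple(toy_scenario.e_adj[i] for i in perm),
            unit_cost=tuple(toy_scenario.unit_cost[i] for i in perm),
        )
        base = compare_strategies(toy_scenario, 0.1, 1000.0)
        moved = compare_strategies(permuted, 0.1, 1000.0)
        b = next(r for r in base if r.strategy == "mainstream")
        m = next(r for r in moved if r.strategy == "mainstream")
        assert b.total_cost == pytest.approx(m.total_cost)
        assert b.lives_saved == pytest.approx(m.lives_saved)
        assert b.cost_per_life_saved == pytest.approx(m.cost_per_life_saved)

    def test_deterministic(self, toy_scenario):
        a = compare_strategies(toy_scenario, 0.1, 1000.0)
        b = compare_strategies(toy_scenario, 0.1, 1000.0)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]
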