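"""Coverage scale-up strategies and cost-effectiveness comparison.

Four strategies allocate the same total number of newly covered pneumonia
episodes (a fixed fraction of the nationally uncovered pool, default 10%):

- ``inequity_promoting``: fill from the wealthiest quintile's uncovered pool
  downward, spilling into the next quintile when one is exhausted;
- ``equity_neutral``: take the band centred at the median of the
  wealth-ordered uncovered distribution;
- ``equity_promoting``: fill from the poorest quintile upward;
- ``mainstream``: distribute proportionally to each quintile's share of
  currently covered episodes (scale-up follows the existing distribution).

Because all strategies cover the same episode count, cost differences
reflect unit costs and lives-saved differences reflect burden, coverage and
effectiveness.  The engine is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .burden_model import CauseTrendModel, CfrModel, burden_table
from .cost_model import CostModel, cost_per_child
from .data_model import CountryDataset
from .effectiveness_model import EffectivenessModel, pif, quintile_effectiveness
from .errors import DomainError, UndefinedResultError

__all__ = [
    "STRATEGIES",
    "AllocationPlan",
    "StrategyResult",
    "Scenario",
    "build_scenario",
    "uncovered",
    "allocate",
    "lives_saved",
    "cost_per_life_saved",
    "lives_for_budget",
    "compare_strategies",
]

STRATEGIES = (
    "mainstream",
    "inequity_promoting",
    "equity_neutral",
    "equity_promoting",
)

#: within-one-episode tolerance for allocation conservation
_EPISODE_TOL = 1.0


@dataclass(frozen=True)
class AllocationPlan:
    """Per-quintile newly covered episodes produced by one strategy."""

    strategy: str
    step: float
    newly_covered: tuple[float, ...]  # episodes, Q1 -> Q5
    delta_coverage: tuple[float, ...]  # fractions, Q1 -> Q5

    @property
    def total_newly_covered(self) -> float:
        return float(sum(self.newly_covered))


@dataclass(frozen=True)
class StrategyResult:
    """Outcome of one strategy on one country."""

    country: str
    strategy: str
    step: float
    total_cost: float
    lives_saved: float
    cost_per_life_saved: float
    budget: float
    lives_for_budget: float
    lives_for_budget_naive: float
    budget_capped: bool

    def to_dict(self) -> dict:
        return {
            "country": self.country,
            "strategy": self.strategy,
            "step": self.step,
            "total_cost": self.total_cost,
            "lives_saved": self.lives_saved,
            "cost_per_life_saved": self.cost_per_life_saved,
            "budget": self.budget,
            "lives_for_budget": self.lives_for_budget,
            "lives_for_budget_naive": self.lives_for_budget_naive,
            "budget_capped": self.budget_capped,
        }


@dataclass(frozen=True)
class Scenario:
    """Fully populated per-quintile inputs for the engine (Q1 -> Q5)."""

    country: str
    u5mr: tuple[float, ...]
    coverage: tuple[float, ...]
    episodes: tuple[float, ...]
    pneumonia_deaths: tuple[float, ...]
    e_adj: tuple[float, ...]  # adjusted effectiveness, percent
    unit_cost: tuple[float, ...]  # US$ per child treated

    def __post_init__(self):
        n = len(self.u5mr)
        for name in ("coverage", "episodes", "pneumonia_deaths", "e_adj",
                     "unit_cost"):
            if len(getattr(self, name)) != n:
                raise DomainError(f"scenario field '{name}' length mismatch")


def build_scenario(
    dataset: CountryDataset,
    cost_model: CostModel,
    eff_model: EffectivenessModel,
    cause_model: CauseTrendModel | None = None,
    cfr_model: CfrModel | None = None,
) -> Scenario:
    """Assemble engine inputs from a dataset and the fitted sub-models."""
    burden = burden_table(dataset, cause_model=cause_model, cfr_model=cfr_model)
    coverage = []
    for q in dataset.quintiles:
        if q.coverage is None:
            raise DomainError(
                f"coverage unset for {dataset.country} Q{q.quintile}"
            )
        coverage.append(q.coverage)
    return Scenario(
        country=dataset.country,
        u5mr=tuple(dataset.u5mr),
        coverage=tuple(coverage),
        episodes=tuple(burden["episodes"]),
        pneumonia_deaths=tuple(burden["pneumonia_deaths"]),
        e_adj=tuple(
            quintile_effectiveness(eff_model, u) for u in dataset.u5mr
        ),
        unit_cost=tuple(cost_per_child(cost_model, u) for u in dataset.u5mr),
    )


def uncovered(
    coverage: Sequence[float], episodes: Sequence[float]
) -> np.ndarray:
    """Per-quintile uncovered episode counts: ``(1 - coverage) * episodes``."""
    cov = np.asarray(coverage, dtype=float)
    eps = np.asarray(episodes, dtype=float)
    if cov.shape != eps.shape:
        raise DomainError("coverage and episodes must have equal length")
    if np.any((cov < 0) | (cov > 1)) or np.any(eps < 0):
        raise DomainError("coverage must lie in [0, 1] and episodes >= 0")
    return (1.0 - cov) * eps


def _fill_ordered(amount, pools, order):
    """Greedy fill of `amount` episodes through `pools` in `order`."""
    out = np.zeros_like(pools)
    remaining = amount
    for i in order:
        take = min(remaining, pools[i])
        out[i] = take
        remaining -= take
        if remaining <= 0:
            break
    return out


def _fill_band(amount, pools):
    """Take the band centred at the median of the wealth-ordered uncovered
    distribution: cumulative interval [0.5 - f/2, 0.5 + f/2], f = amount/total."""
    total = pools.sum()
    f = amount / total
    lo, hi = 0.5 - f / 2.0, 0.5 + f / 2.0
    lo, hi = max(lo, 0.0), min(hi, 1.0)
    edges = np.concatenate([[0.0], np.cumsum(pools) / total])
    out = np.zeros_like(pools)
    for i in range(len(pools)):
        overlap = max(0.0, min(hi, edges[i + 1]) - max(lo, edges[i]))
        out[i] = overlap * total
    return out


def _fill_proportional(amount, pools, weights):
    """Distribute `amount` proportionally to `weights`, capped at each pool,
    redistributing any excess among non-saturated quintiles."""
    out = np.zeros_like(pools)
    active = weights > 0
    remaining = amount
    for _ in range(len(pools) + 1):
        if remaining <= 1e-12 or not active.any():
            break
        w = np.where(active, weights, 0.0)
        share = remaining * w / w.sum()
        room = pools - out
        take = np.minimum(share, room)
        out += take
        remaining -= take.sum()
        active &= (pools - out) > 1e-12
    return out


def _allocate_amount(strategy, amount, pools, covered):
    if strategy == "inequity_promoting":
        return _fill_ordered(amount, pools, range(len(pools)))
    if strategy == "equity_promoting":
        return _fill_ordered(amount, pools, range(len(pools) - 1, -1, -1))
    if strategy == "equity_neutral":
        return _fill_band(amount, pools)
    if strategy == "mainstream":
        weights = np.asarray(covered, dtype=float)
        if weights.sum() == 0:
            warnings.warn(
                "mainstream strategy with zero current coverage everywhere: "
                "falling back to uniform shares",
                stacklevel=3,
            )
            weights = np.ones_like(weights)
        return _fill_proportional(amount, pools, weights)
    raise DomainError(f"unknown strategy {strategy!r}")


def allocate(
    strategy: str,
    step: float,
    uncovered_counts: Sequence[float],
    covered_counts: Sequence[float] | None = None,
) -> AllocationPlan:
    """Allocate ``step`` of the national uncovered pool to quintiles.

    ``covered_counts`` (currently covered episodes per quintile) is required
    for the ``mainstream`` strategy only.

    Raises
    ------
    DomainError
        If ``step`` is outside (0, 1], the uncovered pool is empty, or
        ``mainstream`` is requested without covered counts.
    """
    if not (0.0 < step <= 1.0):
        raise DomainError(f"step must lie in (0, 1], got {step!r}")
    pools = np.asarray(uncovered_counts, dtype=float)
    if np.any(pools < 0):
        raise DomainError("uncovered counts must be >= 0")
    total = pools.sum()
    if total == 0:
        raise DomainError("total uncovered population is zero")
    if strategy == "mainstream" and covered_counts is None:
        raise DomainError("mainstream strategy requires covered counts")
    target = step * total
    newly = _allocate_amount(strategy, target, pools, covered_counts)
    totals = _episode_totals(pools, covered_counts)
    delta = np.divide(
        newly, totals, out=np.zeros_like(newly), where=totals > 0
    )
    return AllocationPlan(
        strategy=strategy,
        step=step,
        newly_covered=tuple(newly.tolist()),
        delta_coverage=tuple(delta.tolist()),
    )


def _episode_totals(pools, covered_counts):
    if covered_counts is None:
        return pools
    return pools + np.asarray(covered_counts, dtype=float)


def lives_saved(
    plan: AllocationPlan,
    coverage: Sequence[float],
    episodes: Sequence[float],
    pneumonia_deaths: Sequence[float],
    e_adj: Sequence[float],
) -> float:
    """Deaths averted by the plan: sum over quintiles of observed pneumonia
    deaths times the potential impact fraction of the coverage change."""
    total = 0.0
    for n_q, c_q, eps_q, d_q, e_q in zip(
        plan.newly_covered, coverage, episodes, pneumonia_deaths, e_adj
    ):
        if n_q == 0 or d_q == 0:
            continue
        if eps_q <= 0:
            raise DomainError("newly covered episodes in an empty quintile")
        dc = n_q / eps_q
        total += d_q * pif(e_q, c_q, min(1.0, c_q + dc))
    return total


def _plan_cost(plan, unit_cost):
    return float(np.dot(plan.newly_covered, unit_cost))


def cost_per_life_saved(
    plan: AllocationPlan, scenario: Scenario
) -> tuple[float, float, float]:
    """Total cost, lives saved and US$ per life saved for a plan.

    Raises
    ------
    UndefinedResultError
        If the plan saves no lives (rather than returning infinity).
    """
    cost = _plan_cost(plan, scenario.unit_cost)
    lives = lives_saved(
        plan,
        scenario.coverage,
        scenario.episodes,
        scenario.pneumonia_deaths,
        scenario.e_adj,
    )
    if lives <= 0:
        raise UndefinedResultError(
            f"plan for {scenario.country}/{plan.strategy} saves no lives; "
            "cost per life saved undefined"
        )
    return cost, lives, cost / lives


def lives_for_budget(
    budget: float, strategy: str, scenario: Scenario
) -> tuple[float, bool]:
    """Lives saved by spending ``budget`` US$ under one strategy.

    Expands the strategy's allocation (greedy in the strategy's quintile
    ordering, fractional coverage allowed) until the budget is exhausted or
    the entire uncovered population is covered.  Returns (lives, capped);
    ``capped`` is True when the budget covers everyone uncovered.
    """
    if budget <= 0:
        raise DomainError(f"budget must be > 0, got {budget!r}")
    pools = uncovered(scenario.coverage, scenario.episodes)
    total = pools.sum()
    if total == 0:
        raise DomainError("no uncovered episodes to expand into")
    covered = np.asarray(scenario.episodes) - pools
    unit = np.asarray(scenario.unit_cost)

    def cost_at(amount):
        n = _allocate_amount(strategy, amount, pools, covered)
        return float(np.dot(n, unit))

    capped = cost_at(total) <= budget
    if capped:
        amount = total
    else:
        lo, hi = 0.0, total
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if cost_at(mid) <= budget:
                lo = mid
            else:
                hi = mid
        amount = lo
    newly = _allocate_amount(strategy, amount, pools, covered)
    plan = AllocationPlan(
        strategy=strategy,
        step=amount / total,
        newly_covered=tuple(newly.tolist()),
        delta_coverage=tuple(
            (newly / np.asarray(scenario.episodes)).tolist()
        ),
    )
    lives = lives_saved(
        plan,
        scenario.coverage,
        scenario.episodes,
        scenario.pneumonia_deaths,
        scenario.e_adj,
    )
    return lives, capped


def compare_strategies(
    scenario: Scenario, step: float = 0.10, budget: float = 1_000_000.0
) -> list[StrategyResult]:
    """Run all four strategies on one country at the same step and budget."""
    pools = uncovered(scenario.coverage, scenario.episodes)
    covered = np.asarray(scenario.episodes) - pools
    results = []
    for strategy in STRATEGIES:
        plan = allocate(strategy, step, pools, covered)
        cost, lives, cpls = cost_per_life_saved(plan, scenario)
        budget_lives, capped = lives_for_budget(budget, strategy, scenario)
        results.append(
            StrategyResult(
                country=scenario.country,
                strategy=strategy,
                step=step,
                total_cost=cost,
                lives_saved=lives,
                cost_per_life_saved=cpls,
                budget=budget,
                lives_for_budget=budget_lives,
                lives_for_budget_naive=budget / cpls,
                budget_capped=capped,
            )
        )
    return results


def results_frame(results: Sequence[StrategyResult]) -> pd.DataFrame:
    """Tabulate StrategyResults for CSV output."""
    return pd.DataFrame([r.to_dict() for r in results])
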