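"""Decision-analytic layer: ACERs, the efficient frontier, ICERs, sweeps.

Strategies are compared on (discounted) cost and QALY per 1000 persons.
Average cost-effectiveness ratios (ACERs) are taken against no screening;
incremental ratios (ICERs) are assessed only among strategies on the
efficient frontier — those not strongly dominated (another strategy is no
more costly and at least as effective) nor extendedly dominated (a mix of
two other strategies does better) — each relative to the next less
effective frontier strategy.  The frontier is computed on discounted
values.

The module also runs directly on externally supplied cost/LY/QALY tables
(the packaged strategy-table fixture), which is how the published decision
layer is reproduced without the unpublished calibrated simulator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .economics import (
    ALL_COMPONENTS,
    CancerCareParams,
    RR_GRID,
    ScenarioAssumptions,
    StrategyResult,
    summarize_arm,
)
from .natural_history import DiseaseParams, LifeTable, simulate_cohort
from .population_inputs import AgeCurve
from .screening import Strategy, run_arm

__all__ = [
    "CEPoint",
    "FrontierReport",
    "acer",
    "efficient_frontier",
    "icer_table",
    "load_table1_fixture",
    "frontier_from_table",
    "scenario_sweep",
    "sensitivity_suite",
    "COST_SAVING",
    "DOMINATED",
]

COST_SAVING = "cost-saving"
DOMINATED = "dominated"


@dataclass(frozen=True)
class CEPoint:
    """One strategy's (cost, QALY) position, in dollars and QALYs per 1000."""

    label: str
    cost: float
    qaly: float
    ly: float = float("nan")

    @classmethod
    def from_result(cls, r: StrategyResult) -> "CEPoint":
        return cls(label=r.label, cost=r.cost, qaly=r.qaly, ly=r.ly)


@dataclass
class FrontierReport:
    """Dominance labels, frontier ICERs and ACERs for a strategy set."""

    points: list[CEPoint]
    labels: dict[str, str]  # label -> efficient | strongly_dominated |
    #                                  extendedly_dominated | reference
    icers: dict[str, float]  # efficient non-reference label -> $/QALY
    reference: str
    acers: dict[str, object] = field(default_factory=dict)

    @property
    def efficient(self) -> list[CEPoint]:
        order = sorted(
            (p for p in self.points if self.labels[p.label] in ("efficient", "reference")),
            key=lambda p: (p.cost, p.qaly),
        )
        return order

    def efficient_labels(self) -> set[str]:
        return {p.label for p in self.efficient}


def acer(result, comparator):
    """Average cost-effectiveness ratio vs a fixed comparator.

    Returns dollars per QALY gained; the string ``cost-saving`` when the
    strategy costs less and gains QALYs; the string ``dominated`` when it
    gains no QALYs.
    """
    d_cost = result.cost - comparator.cost
    d_qaly = result.qaly - comparator.qaly
    if d_qaly <= 0:
        return DOMINATED
    if d_cost < 0:
        return COST_SAVING
    return d_cost / d_qaly


def efficient_frontier(
    points: Sequence[CEPoint], comparator_label: str | None = None
) -> FrontierReport:
    """Dominance analysis of a strategy set.

    Sort by cost; drop strongly dominated points (some other point is no
    more costly and no less effective, with one strict inequality — exact
    ties keep the lexicographically smallest label); then repeatedly drop
    extendedly dominated points until the ICERs along the frontier are
    strictly increasing.  The least costly remaining point is the
    reference.  If ``comparator_label`` names a point, ACERs against it are
    attached for every other point.
    """
    if len(points) == 0:
        raise ValueError("need at least one strategy")
    labels: dict[str, str] = {}
    pts = sorted(points, key=lambda p: (p.cost, -p.qaly, p.label))

    # strong dominance (including duplicate-point tie-break on label)
    alive: list[CEPoint] = []
    for p in pts:
        dominated = False
        for q in pts:
            if q is p:
                continue
            if q.cost <= p.cost and q.qaly >= p.qaly:
                if q.cost < p.cost or q.qaly > p.qaly:
                    dominated = True
                    break
                if q.label < p.label:  # exact duplicate: keep smallest label
                    dominated = True
                    break
        if dominated:
            labels[p.label] = "strongly_dominated"
        else:
            alive.append(p)

    # extended dominance: prune until ICERs strictly increase
    chain = sorted(alive, key=lambda p: (p.cost, p.qaly))
    changed = True
    while changed and len(chain) > 2:
        changed = False
        for i in range(1, len(chain) - 1):
            lo, mid, hi = chain[i - 1], chain[i], chain[i + 1]
            icer_in = (mid.cost - lo.cost) / (mid.qaly - lo.qaly)
            icer_out = (hi.cost - mid.cost) / (hi.qaly - mid.qaly)
            if icer_in >= icer_out:
                labels[mid.label] = "extendedly_dominated"
                del chain[i]
                changed = True
                break

    icers: dict[str, float] = {}
    for prev, cur in zip(chain[:-1], chain[1:]):
        icers[cur.label] = (cur.cost - prev.cost) / (cur.qaly - prev.qaly)
    labels[chain[0].label] = "reference"
    for p in chain[1:]:
        labels[p.label] = "efficient"

    report = FrontierReport(
        points=list(points), labels=labels, icers=icers, reference=chain[0].label
    )
    if comparator_label is not None:
        comp = next(p for p in points if p.label == comparator_label)
        report.acers = {
            p.label: acer(p, comp) for p in points if p.label != comparator_label
        }
    return report


def icer_table(report: FrontierReport) -> list[tuple[str, float]]:
    """(strategy, ICER) pairs along the frontier, least to most effective."""
    return [(p.label, report.icers[p.label]) for p in report.efficient[1:]]


# ---------------------------------------------------------------------------
# published strategy-table fixture

_SCENARIO_COLS = ("default", "100", "125", "150")


def load_table1_fixture(path=None) -> pd.DataFrame:
    """Tidy view of the packaged published strategy table.

    Returns one row per (disease, scenario, strategy) with columns
    ``cost`` (dollars per 1000 persons), ``ly``, ``qaly`` and
    ``icer_printed`` (dollars per QALY; NaN for reference/dominated rows).
    Colorectal cost cells are printed in $ millions, esophageal cost cells
    in $ thousands, per 1000 persons; both are converted to dollars here.
    """
    if path is None:
        path = importlib.resources.files("screencea").joinpath("data/table1_fixture.csv")
    raw = pd.read_csv(path, comment="#")
    rows = []
    for _, r in raw.iterrows():
        unit = 1e6 if r["disease"] == "crc" else 1e3
        for scen in _SCENARIO_COLS:
            icer = r[f"icer_{scen}"]
            rows.append(
                {
                    "disease": r["disease"],
                    "scenario": scen,
                    "strategy": r["strategy"],
                    "cost": float(r[f"cost_{scen}"]) * unit,
                    "ly": float(r[f"ly_{scen}"]),
                    "qaly": float(r[f"qaly_{scen}"]),
                    "icer_printed": float(icer) if _is_number(icer) else np.nan,
                    "flag_printed": str(icer),
                }
            )
    return pd.DataFrame(rows)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def frontier_from_table(
    table: pd.DataFrame, disease: str, scenario: str
) -> FrontierReport:
    """Frontier analysis of one (disease, scenario) column of the fixture."""
    sub = table[(table.disease == disease) & (table.scenario == scenario)]
    points = [
        CEPoint(label=r.strategy, cost=r.cost, qaly=r.qaly, ly=r.ly)
        for r in sub.itertuples()
    ]
    return efficient_frontier(points, comparator_label="No screening")


# ---------------------------------------------------------------------------
# scenario sweeps on the simulator

def _scenario_grid(rr_grid, discount_rate, excess_only) -> list[ScenarioAssumptions]:
    cells = [
        ScenarioAssumptions.default(discount_rate),
        ScenarioAssumptions.average(discount_rate, excess_only),
    ]
    for comp in sorted(ALL_COMPONENTS):
        for rr in rr_grid:
            if rr == 1.0:
                continue  # identical to the all-average cell
            cells.append(ScenarioAssumptions.single(comp, rr, discount_rate, excess_only))
    for rr in rr_grid:
        if rr == 1.0:
            continue
        cells.append(ScenarioAssumptions.combined(rr, discount_rate, excess_only))
    return cells


def scenario_sweep(
    n: int,
    disease_params: DiseaseParams,
    life_table: LifeTable,
    strategies: Sequence[Strategy],
    cost_curve: AgeCurve | None,
    utility_curve: AgeCurve | None,
    care: CancerCareParams,
    seed: int,
    *,
    entry_age: float = 40.0,
    rr_grid: Sequence[float] = RR_GRID,
    discount_rate: float = 0.03,
    excess_only: bool = False,
    scenarios: Sequence[ScenarioAssumptions] | None = None,
) -> pd.DataFrame:
    """One full CEA per scenario cell, sharing random numbers across cells.

    Returns a tidy table with one row per (scenario, strategy): discounted
    cost/LY/QALY per 1000, the ACER vs no screening, and the frontier label
    and ICER within the scenario.  Cohorts are re-simulated only when the
    scenario's mortality relative risk changes; all other assumption
    changes re-weight the same histories.
    """
    if scenarios is None:
        scenarios = _scenario_grid(rr_grid, discount_rate, excess_only)

    cohort_cache: dict[float, list] = {}
    arm_cache: dict[tuple[float, str], list] = {}

    def arms_for(rr_m: float):
        if rr_m not in cohort_cache:
            cohort_cache[rr_m] = simulate_cohort(
                n, disease_params, life_table, rr_m, seed, entry_age=entry_age
            )
        cohort = cohort_cache[rr_m]
        out = {}
        for strat in strategies:
            key = (rr_m, strat.label)
            if key not in arm_cache:
                arm_cache[key] = run_arm(cohort, strat, seed, disease_params)
            out[strat.label] = arm_cache[key]
        return out

    rows = []
    for scen in scenarios:
        arms = arms_for(scen.rr_mortality)
        results = {
            label: summarize_arm(arm, cost_curve, utility_curve, care, scen, label=label)
            for label, arm in arms.items()
        }
        comparator = results.get("No screening")
        points = [CEPoint.from_result(r) for r in results.values()]
        report = efficient_frontier(
            points, comparator_label="No screening" if comparator else None
        )
        for label, r in results.items():
            a = report.acers.get(label) if comparator else None
            rows.append(
                {
                    "scenario": scen.label,
                    "rr": scen.rr,
                    "components": "+".join(sorted(scen.components)) or "none",
                    "include_background": scen.include_background,
                    "discount_rate": scen.discount_rate,
                    "excess_only": scen.excess_only,
                    "strategy": label,
                    "cost": r.cost,
                    "ly": r.ly,
                    "qaly": r.qaly,
                    "acer": a if isinstance(a, (int, float)) else np.nan,
                    "acer_flag": a if isinstance(a, str) else "",
                    "frontier_label": report.labels[label],
                    "icer": report.icers.get(label, np.nan),
                }
            )
    return pd.DataFrame(rows)


def sensitivity_suite(
    n: int,
    disease_params: DiseaseParams,
    life_table: LifeTable,
    strategies: Sequence[Strategy],
    cost_curve: AgeCurve | None,
    utility_curve: AgeCurve | None,
    care: CancerCareParams,
    seed: int,
    *,
    entry_age: float = 40.0,
    rr_grid: Sequence[float] = RR_GRID,
) -> dict[str, pd.DataFrame]:
    """Re-run the sweep with 0% discounting and with excess-only expenses."""
    common = dict(
        n=n,
        disease_params=disease_params,
        life_table=life_table,
        strategies=strategies,
        cost_curve=cost_curve,
        utility_curve=utility_curve,
        care=care,
        seed=seed,
        entry_age=entry_age,
        rr_grid=rr_grid,
    )
    return {
        "undiscounted": scenario_sweep(discount_rate=0.0, **common),
        "excess_only": scenario_sweep(excess_only=True, **common),
    }
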