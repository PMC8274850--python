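"""Discounted life-year, QALY and cost accrual under scenario assumptions.

Turns (screened) person histories into per-strategy discounted costs,
life-years and QALYs.  The scenario object carries the assumption machinery
under study: whether background (non-target-condition) health expenditures
and disutility are counted at all, and by how much they — and other-cause
mortality — are inflated for persons carrying precancerous lesions or
cancer, via a relative-risk multiplier applied to population-average age
curves.

Quality weight of a life-year at age a:

    default scenario:        w = 1 - cancer_decrement
    background, unscaled:    w = u(a) - cancer_decrement
    background, RR applies:  w = 1 - rr * (1 - u(a)) - cancer_decrement

clipped to [0, 1].  Background cost rate is rr * c(a) (or (rr-1) * c(a)
when only excess expenses are counted).  The RR applies from first
precursor onset onward (or lifelong, by configuration).

Discounting starts at cohort entry, continuously: present value of an
accrual at age a is x * (1+r)^{-(a - entry)}; continuous accruals are
integrated exactly (Gauss-Legendre on the smooth segments between event
breakpoints; no cycle approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .population_inputs import AgeCurve
from .screening import ScreenedHistory

__all__ = [
    "ScenarioAssumptions",
    "CancerCareParams",
    "PersonAccrual",
    "StrategyResult",
    "discount",
    "quality_weight",
    "accrue_person",
    "summarize_arm",
]

RR_GRID = (1.0, 1.125, 1.25, 1.375, 1.5)
ALL_COMPONENTS = frozenset({"costs", "disutility", "mortality"})

# 16-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0


@dataclass(frozen=True)
class ScenarioAssumptions:
    """One cell of the assumption grid.

    ``components`` names which of {costs, disutility, mortality} are scaled
    by ``rr`` for lesion-bearing persons; components not named stay at the
    population average.  ``include_background`` switches background costs
    and disutility on at all — the default scenario has it off (average
    mortality, no other-condition costs or disutility).
    """

    rr: float = 1.25
    components: frozenset[str] = frozenset()
    include_background: bool = False
    discount_rate: float = 0.03
    excess_only: bool = False
    rr_onset_rule: str = "from_first_lesion"
    label: str = ""

    def __post_init__(self):
        if self.rr < 1.0:
            raise ValueError("relative-risk multiplier must be >= 1")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        unknown = set(self.components) - ALL_COMPONENTS
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        if self.rr_onset_rule not in ("from_first_lesion", "lifelong"):
            raise ValueError(f"unknown rr_onset_rule: {self.rr_onset_rule!r}")

    @property
    def rr_mortality(self) -> float:
        return self.rr if "mortality" in self.components else 1.0

    @property
    def rr_costs(self) -> float:
        return self.rr if "costs" in self.components else 1.0

    @property
    def rr_disutility(self) -> float:
        return self.rr if "disutility" in self.components else 1.0

    @classmethod
    def default(cls, discount_rate: float = 0.03) -> "ScenarioAssumptions":
        """Average mortality; no background costs or disutility."""
        return cls(rr=1.0, include_background=False, discount_rate=discount_rate,
                   label="default")

    @classmethod
    def average(cls, discount_rate: float = 0.03, excess_only: bool = False):
        """All components at the population average (rr effectively 1)."""
        return cls(rr=1.0, components=ALL_COMPONENTS, include_background=True,
                   discount_rate=discount_rate, excess_only=excess_only, label="average")

    @classmethod
    def single(cls, component: str, rr: float, discount_rate: float = 0.03,
               excess_only: bool = False):
        """Background on; one component scaled to rr, the rest at average."""
        return cls(rr=rr, components=frozenset({component}), include_background=True,
                   discount_rate=discount_rate, excess_only=excess_only,
                   label=f"{component}@{rr:g}")

    @classmethod
    def combined(cls, rr: float, discount_rate: float = 0.03, excess_only: bool = False):
        return cls(rr=rr, components=ALL_COMPONENTS, include_background=True,
                   discount_rate=discount_rate, excess_only=excess_only,
                   label=f"combined@{rr:g}")


@dataclass(frozen=True)
class CancerCareParams:
    """Costs and disutilities of screening-detected disease and its care.

    Treatment cost is stage-specific and falls at diagnosis; a terminal-care
    cost falls at cancer death.  Diagnosed patients carry a utility
    decrement for ``decrement_duration`` years (truncated at death).
    """

    treatment_cost_by_stage: tuple[float, ...] = (30_000.0, 60_000.0, 90_000.0, 120_000.0)
    terminal_cost: float = 60_000.0
    cancer_decrement: float = 0.12
    decrement_duration: float = 3.0

    def __post_init__(self):
        if any(c < 0 for c in self.treatment_cost_by_stage) or self.terminal_cost < 0:
            raise ValueError("costs must be >= 0")
        if not 0 <= self.cancer_decrement <= 1:
            raise ValueError("utility decrement must lie in [0, 1]")


@dataclass
class PersonAccrual:
    cost: float = 0.0
    ly: float = 0.0
    qaly: float = 0.0
    disutility: float = 0.0  # integrated + lump disutility; qaly == ly - disutility
    cost_undiscounted: float = 0.0
    ly_undiscounted: float = 0.0
    qaly_undiscounted: float = 0.0


@dataclass(frozen=True)
class StrategyResult:
    """Per-1000-person discounted (and undiscounted) totals for one strategy."""

    label: str
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float
    n_persons: int


def discount(amount: float, time_since_entry: float, rate: float) -> float:
    """Present value of a point accrual: amount / (1+rate)^time."""
    if time_since_entry < 0:
        raise ValueError("time since cohort entry must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return amount / (1.0 + rate) ** time_since_entry


def quality_weight(
    age: float,
    utility_curve: AgeCurve | None,
    scenario: ScenarioAssumptions,
    has_lesion: bool,
    cancer_decrement: float = 0.0,
) -> float:
    """Quality weight of a life-year at ``age`` under the scenario rules."""
    if not scenario.include_background or utility_curve is None:
        w = 1.0 - cancer_decrement
    else:
        u = utility_curve(age)
        rr_applies = has_lesion or scenario.rr_onset_rule == "lifelong"
        kappa = scenario.rr_disutility if rr_applies else 1.0
        w = 1.0 - kappa * (1.0 - u) - cancer_decrement
    return float(np.clip(w, 0.0, 1.0))


def _segment_breaks(entry, death, first_lesion, dx_age, dec_end, curves):
    pts = {entry, death}
    for a in (first_lesion, dx_age, dec_end):
        if a is not None and entry < a < death:
            pts.add(float(a))
    for curve in curves:
        if curve is not None:
            for edge in curve.domain:
                if entry < edge < death:
                    pts.add(float(edge))
    return sorted(pts)


def accrue_person(
    sh: ScreenedHistory,
    cost_curve: AgeCurve | None,
    utility_curve: AgeCurve | None,
    care: CancerCareParams,
    scenario: ScenarioAssumptions,
) -> PersonAccrual:
    """Integrate one person's discounted cost, LY and QALY from entry to death.

    Continuous background accruals are integrated segment-wise with
    Gauss-Legendre quadrature between the breakpoints where the integrand
    changes regime (first lesion onset, diagnosis, end of the cancer-related
    utility decrement, curve domain edges); event costs and disutilities are
    discounted at their event ages.
    """
    entry = sh.entry_age
    death = sh.observed_death_age
    rate = scenario.discount_rate
    rho = np.log1p(rate)
    out = PersonAccrual()

    fl = sh.first_lesion_age
    dx = sh.diagnosis_age
    dec_end = None
    if dx is not None:
        dec_end = min(dx + care.decrement_duration, death)

    if death > entry:
        breaks = _segment_breaks(entry, death, fl, dx, dec_end, (cost_curve, utility_curve))
        for a0, a1 in zip(breaks[:-1], breaks[1:]):
            mid = 0.5 * (a0 + a1)
            has_lesion = fl is not None and mid >= fl
            in_decrement = dx is not None and dx <= mid < (dec_end or dx)
            dec = care.cancer_decrement if in_decrement else 0.0

            nodes = a0 + (a1 - a0) * _GL_X
            w_quad = (a1 - a0) * _GL_W
            df = np.exp(-rho * (nodes - entry))

            # quality weight at the nodes
            if not scenario.include_background or utility_curve is None:
                w = np.full_like(nodes, 1.0 - dec)
            else:
                u = utility_curve(nodes)
                rr_applies = has_lesion or scenario.rr_onset_rule == "lifelong"
                kappa = scenario.rr_disutility if rr_applies else 1.0
                w = 1.0 - kappa * (1.0 - u) - dec
            w = np.clip(w, 0.0, 1.0)

            # background cost rate at the nodes
            if scenario.include_background and cost_curve is not None:
                rr_applies = has_lesion or scenario.rr_onset_rule == "lifelong"
                kappa_c = scenario.rr_costs if rr_applies else 1.0
                mult = (kappa_c - 1.0) if scenario.excess_only else kappa_c
                c = mult * cost_curve(nodes)
            else:
                c = np.zeros_like(nodes)

            out.ly += float(np.sum(w_quad * df))
            out.ly_undiscounted += float(a1 - a0)
            out.qaly += float(np.sum(w_quad * w * df))
            out.qaly_undiscounted += float(np.sum(w_quad * w))
            out.disutility += float(np.sum(w_quad * (1.0 - w) * df))
            out.cost += float(np.sum(w_quad * c * df))
            out.cost_undiscounted += float(np.sum(w_quad * c))

    # event costs and disutility lumps
    for ev in sh.events:
        t = max(ev.age - entry, 0.0)
        out.cost += discount(ev.cost, t, rate)
        out.cost_undiscounted += ev.cost
        out.qaly -= discount(ev.disutility, t, rate)
        out.qaly_undiscounted -= ev.disutility
        out.disutility += discount(ev.disutility, t, rate)

    if dx is not None:
        stage = sh.diagnosis_stage if sh.diagnosis_stage is not None else 0
        tc = care.treatment_cost_by_stage[min(stage, len(care.treatment_cost_by_stage) - 1)]
        out.cost += discount(tc, dx - entry, rate)
        out.cost_undiscounted += tc
    if sh.died_of_cancer:
        out.cost += discount(care.terminal_cost, sh.cancer_death_age - entry, rate)
        out.cost_undiscounted += care.terminal_cost
    return out


def summarize_arm(
    arm: Sequence[ScreenedHistory],
    cost_curve: AgeCurve | None,
    utility_curve: AgeCurve | None,
    care: CancerCareParams,
    scenario: ScenarioAssumptions,
    label: str = "",
) -> StrategyResult:
    """Per-1000-person scaling of summed accruals, discounted and undiscounted."""
    if len(arm) == 0:
        raise ValueError("cannot summarize an empty arm")
    scale = 1000.0 / len(arm)
    tot = PersonAccrual()
    for sh in arm:
        a = accrue_person(sh, cost_curve, utility_curve, care, scenario)
        tot.cost += a.cost
        tot.ly += a.ly
        tot.qaly += a.qaly
        tot.cost_undiscounted += a.cost_undiscounted
        tot.ly_undiscounted += a.ly_undiscounted
        tot.qaly_undiscounted += a.qaly_undiscounted
    return StrategyResult(
        label=label,
        cost=tot.cost * scale,
        ly=tot.ly * scale,
        qaly=tot.qaly * scale,
        cost_undiscounted=tot.cost_undiscounted * scale,
        ly_undiscounted=tot.ly_undiscounted * scale,
        qaly_undiscounted=tot.qaly_undiscounted * scale,
        n_persons=len(arm),
    )
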