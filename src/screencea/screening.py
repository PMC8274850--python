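"""Application of screening strategies to simulated natural histories.

A strategy schedules tests between its start and stop ages; at each contact
every extant lesion may be detected with a state-specific sensitivity.
Detected precursor lesions are removed (their future malignant path is
cancelled) and the person enters surveillance; detected preclinical cancer
is diagnosed early with a stage-shifted distribution and its survival
re-drawn from the shifted stage's curve, using a reserved random stream so
the no-screening arm is unaffected.  Lesion-free persons may test falsely
positive at 1 - specificity (a cost consequence only).

Common random numbers: the natural-history draws live in the cohort and
are shared across arms; screening draws come from per-person streams keyed
only by (seed, person, purpose), never by strategy.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numpy.random import Generator

from .natural_history import (
    DiseaseParams,
    Lesion,
    PersonHistory,
    PURPOSE_SCREENING,
    PURPOSE_STAGE_SHIFT,
    person_rng,
    resolve_death,
)

__all__ = [
    "TestCharacteristics",
    "SurveillanceRule",
    "Strategy",
    "ScreenEvent",
    "ScreenedHistory",
    "schedule_screens",
    "apply_strategy",
    "run_arm",
    "as_screened",
]

COMPLICATION_DISUTILITY = 0.01  # QALY lump per procedural complication


@dataclass(frozen=True)
class TestCharacteristics:
    """Per-state sensitivity, specificity, and the test's cost/harm profile.

    ``triage`` models two-step testing (cytosponge with endoscopic follow-up
    of positives): the primary test flags a lesion, the triage test must
    confirm it, so effective sensitivity is the product of the two.
    """

    sensitivity: Mapping[str, float]
    specificity: float
    cost: float
    complication_prob: float = 0.0
    complication_cost: float = 0.0
    removal_cost: float = 0.0
    disutility: float = 0.0  # QALY lump per test performed
    triage: "TestCharacteristics | None" = None

    def __post_init__(self):
        probs = list(self.sensitivity.values()) + [self.specificity, self.complication_prob]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("test probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SurveillanceRule:
    """Follow-up exams after a positive screen: 3 vs 5 years by risk.

    High risk means any detected lesion in one of ``high_risk_states``
    (most-advanced precursor states, e.g. a large adenoma or high-grade
    dysplasia).  Surveillance continues to stop_age + grace.
    """

    high_risk_interval: float = 3.0
    low_risk_interval: float = 5.0
    high_risk_states: tuple[str, ...] = ()
    grace: float = 0.0

    def __post_init__(self):
        if self.high_risk_interval <= 0 or self.low_risk_interval <= 0:
            raise ValueError("surveillance intervals must be positive")
        if self.high_risk_interval > self.low_risk_interval:
            raise ValueError("high-risk interval must not exceed low-risk interval")


@dataclass(frozen=True)
class Strategy:
    """A screening strategy: modality, ages, interval and test profile."""

    label: str
    modality: str  # {"none", "colonoscopy", "endoscopy", "cytosponge_then_endoscopy"}
    start_age: float
    stop_age: float
    interval: float | None = None  # None = once only
    test: TestCharacteristics | None = None
    surveillance: SurveillanceRule | None = None

    def __post_init__(self):
        if self.start_age > self.stop_age:
            raise ValueError("start_age must be <= stop_age")
        if self.interval is not None and self.interval <= 0:
            raise ValueError("interval must be > 0 (or None for once-only)")

    @property
    def once_only(self) -> bool:
        return self.interval is None


@dataclass(frozen=True)
class ScreenEvent:
    """One dated screening-related event with its cost/disutility consequence."""

    age: float
    kind: str  # screen | surveillance | positive | precursor_removed |
    #            screen_detected_cancer | complication | false_positive
    cost: float = 0.0
    disutility: float = 0.0


@dataclass
class ScreenedHistory:
    """A person's history after a screening strategy has acted on it."""

    base: PersonHistory
    events: list[ScreenEvent] = field(default_factory=list)
    removed_lesions: frozenset = frozenset()
    lesion_overrides: dict = field(default_factory=dict)  # lesion index -> Lesion
    cancer_death_age: float | None = None
    observed_death_age: float = 0.0
    diagnosis_age: float | None = None
    diagnosis_stage: int | None = None
    screen_detected: bool = False

    @property
    def entry_age(self) -> float:
        return self.base.entry_age

    @property
    def first_lesion_age(self) -> float | None:
        # lesion removal does not undo the elevated-morbidity phenotype, so
        # relative-risk onset keys on the underlying first onset during life
        ages = [l.onset_age for l in self.base.lesions if l.onset_age < self.observed_death_age]
        return min(ages) if ages else None

    @property
    def died_of_cancer(self) -> bool:
        return self.cancer_death_age is not None

    def effective_lesions(self) -> list[Lesion]:
        out = []
        for i, les in enumerate(self.base.lesions):
            if i in self.removed_lesions:
                continue
            out.append(self.lesion_overrides.get(i, les))
        return out


def as_screened(history: PersonHistory) -> ScreenedHistory:
    """Wrap an unscreened history in the common arm record type."""
    dx = history.clinical_diagnoses
    return ScreenedHistory(
        base=history,
        cancer_death_age=history.cancer_death_age,
        observed_death_age=history.observed_death_age,
        diagnosis_age=dx[0].clinical_age if dx else None,
        diagnosis_stage=dx[0].stage if dx else None,
    )


def schedule_screens(strategy: Strategy, history: PersonHistory) -> list[float]:
    """Routine screening ages: start, start+interval, ... <= stop, truncated at death."""
    if strategy.modality == "none":
        return []
    if strategy.once_only:
        ages = [strategy.start_age]
    else:
        ages = list(
            np.arange(strategy.start_age, strategy.stop_age + 1e-9, strategy.interval)
        )
    return [float(a) for a in ages if a < history.observed_death_age]


def _draw_categorical(rng: Generator, dist) -> int:
    u = rng.random()
    c = 0.0
    for i, p in enumerate(dist):
        c += p
        if u < c:
            return i
    return len(dist) - 1


def apply_strategy(
    history: PersonHistory,
    strategy: Strategy,
    disease_params: DiseaseParams,
    rng: Generator,
    stage_rng: Generator | None = None,
) -> ScreenedHistory:
    """Run one person through a strategy's screens and surveillance.

    ``rng`` drives detection, false positives and complications; the
    reserved ``stage_rng`` (defaults to ``rng``) drives the stage shift and
    survival re-draw of screen-detected cancers.
    """
    if stage_rng is None:
        stage_rng = rng
    routine = schedule_screens(strategy, history)
    if strategy.modality == "none" or strategy.test is None or not routine:
        return as_screened(history)

    test = strategy.test
    surv_rule = strategy.surveillance
    state_names = disease_params.precursor_states
    ocd = history.other_cause_death_age
    events: list[ScreenEvent] = []
    removed: set[int] = set()
    overrides: dict[int, Lesion] = {}

    def current_state():
        lesions = [
            overrides.get(i, l) for i, l in enumerate(history.lesions) if i not in removed
        ]
        cancer_death, death = resolve_death(lesions, ocd)
        clin = [
            l.clinical_age
            for l in lesions
            if l.clinical_age is not None and l.clinical_age < death
        ]
        return cancer_death, death, (min(clin) if clin else np.inf)

    queue: list[tuple[float, int]] = [(a, 0) for a in routine]
    heapq.heapify(queue)
    in_surveillance = False
    surv_stop = strategy.stop_age + (surv_rule.grace if surv_rule else 0.0)

    while queue:
        t, is_surv = heapq.heappop(queue)
        if in_surveillance and not is_surv:
            continue  # routine screens are superseded by surveillance
        _, death, first_clin = current_state()
        if t >= death or t >= first_clin:
            break  # person dead or already a (symptomatic) cancer patient

        kind = "surveillance" if is_surv else "screen"
        events.append(ScreenEvent(t, kind, cost=test.cost, disutility=test.disutility))

        # lesions present at this contact, with their current state name
        present: list[tuple[int, str]] = []
        for i, les in enumerate(history.lesions):
            if i in removed or i in overrides:
                continue
            comp, k = les.state_at(t)
            if comp == "precursor":
                present.append((i, state_names[min(k, len(state_names) - 1)]))
            elif comp == "preclinical":
                present.append((i, "preclinical"))

        detected: list[tuple[int, str]] = []
        any_primary_positive = False
        if present:
            for i, state_name in present:
                if rng.random() >= test.sensitivity.get(state_name, 0.0):
                    continue
                any_primary_positive = True
                if test.triage is not None:
                    if rng.random() >= test.triage.sensitivity.get(state_name, 0.0):
                        continue
                detected.append((i, state_name))
        else:
            if rng.random() >= test.specificity:
                any_primary_positive = True
                events.append(ScreenEvent(t, "false_positive"))

        if test.triage is not None and any_primary_positive:
            # positive primary test -> triage endoscopy in the same year
            events.append(
                ScreenEvent(t, "positive", cost=test.triage.cost, disutility=test.triage.disutility)
            )
            invasive = test.triage
        else:
            invasive = test
        if invasive.complication_prob > 0 and rng.random() < invasive.complication_prob:
            events.append(
                ScreenEvent(
                    t,
                    "complication",
                    cost=invasive.complication_cost,
                    disutility=COMPLICATION_DISUTILITY,
                )
            )

        if detected:
            preclin = [i for i, s in detected if s == "preclinical"]
            precursors = [(i, s) for i, s in detected if s != "preclinical"]
            for i, _s in precursors:
                removed.add(i)
                events.append(ScreenEvent(t, "precursor_removed", cost=invasive.removal_cost))
            if preclin:
                # earliest preclinical lesion is diagnosed, stage-shifted
                i = min(preclin, key=lambda j: history.lesions[j].preclinical_age)
                stage = _draw_categorical(stage_rng, disease_params.screen_stage_shift)
                surv = stage_rng.exponential(disease_params.cancer_survival_means[stage])
                overrides[i] = replace(
                    history.lesions[i], clinical_age=t, stage=stage, cancer_death_age=t + surv
                )
                events.append(ScreenEvent(t, "screen_detected_cancer"))
                break  # screening program ends at cancer diagnosis
            if surv_rule is not None:
                in_surveillance = True
                high = any(s in surv_rule.high_risk_states for _, s in precursors)
                nxt = t + (surv_rule.high_risk_interval if high else surv_rule.low_risk_interval)
                if nxt <= surv_stop:
                    heapq.heappush(queue, (nxt, 1))
        elif is_surv and surv_rule is not None:
            # clean surveillance exam: continue at the low-risk interval
            nxt = t + surv_rule.low_risk_interval
            if nxt <= surv_stop:
                heapq.heappush(queue, (nxt, 1))

    cancer_death, death, _ = current_state()
    sh = ScreenedHistory(
        base=history,
        events=sorted(
            (e for e in events if e.age <= death), key=lambda e: (e.age, e.kind)
        ),
        removed_lesions=frozenset(removed),
        lesion_overrides=overrides,
        cancer_death_age=cancer_death,
        observed_death_age=death,
    )
    dx = [
        l
        for l in sh.effective_lesions()
        if l.clinical_age is not None and l.clinical_age < death
    ]
    if dx:
        first = min(dx, key=lambda l: l.clinical_age)
        sh.diagnosis_age = first.clinical_age
        sh.diagnosis_stage = first.stage
        sh.screen_detected = any(ov is first for ov in overrides.values())
    return sh


def run_arm(
    cohort: Sequence[PersonHistory],
    strategy: Strategy,
    rng_seed: int,
    disease_params: DiseaseParams | None = None,
) -> list[ScreenedHistory]:
    """Apply a strategy to a whole cohort with strategy-independent streams.

    Person ``i``'s screening draws come from ``person_rng(rng_seed, i,
    PURPOSE_SCREENING)`` and stage-shift redraws from the reserved
    ``PURPOSE_STAGE_SHIFT`` stream, so paired differences between arms are
    low-variance (common random numbers).
    """
    if strategy.modality == "none":
        return [as_screened(h) for h in cohort]
    if disease_params is None:
        raise ValueError("disease_params required for an active screening strategy")
    out = []
    for h in cohort:
        rng = person_rng(rng_seed, h.person_id, PURPOSE_SCREENING)
        stage_rng = person_rng(rng_seed, h.person_id, PURPOSE_STAGE_SHIFT)
        out.append(apply_strategy(h, strategy, disease_params, rng, stage_rng))
    return out
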