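"""Continuous-time person-level natural history of precursor-to-cancer disease.

Simulates birth-to-death life histories through benign precursor states
(e.g. small/medium/large adenoma, or Barrett's esophagus with increasing
dysplasia grade), a preclinical screen-detectable cancer phase, and clinical
cancer, competing with other-cause death drawn from a life table whose
hazard may be scaled by a relative-risk multiplier for persons carrying
lesions.

All times are continuous ages in years.  Competing risks are resolved by
comparing event times directly; there is no cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import Generator, PCG64, SeedSequence

__all__ = [
    "LifeTable",
    "DiseaseParams",
    "Lesion",
    "PersonHistory",
    "sample_other_cause_death",
    "simulate_person",
    "simulate_cohort",
    "person_rng",
]

# purpose codes for per-person random sub-streams; screening reserves 2 and 3
PURPOSE_NATURAL_HISTORY = 0
PURPOSE_SCREENING = 2
PURPOSE_STAGE_SHIFT = 3


def person_rng(seed: int, person_id: int, purpose: int) -> Generator:
    """Deterministic per-person, per-purpose random stream.

    Streams are keyed by (master seed, person index, purpose) so that
    natural-history draws are bit-identical across screening arms (common
    random numbers) and screening draws are strategy-independent.
    """
    return Generator(PCG64(SeedSequence(entropy=(int(seed), int(person_id), int(purpose)))))


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed survival S(a) of the reference population, ages 0..110.

    Survival is interpolated log-linearly within years (piecewise-constant
    hazard), which makes quantile lookups exact inverses of evaluations.
    """

    ages: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "survival", surv)
        if ages.shape != surv.shape or ages.ndim != 1:
            raise ValueError("ages and survival must be 1-d arrays of equal length")
        if ages[0] != 0:
            raise ValueError("life table must start at age 0")
        if abs(surv[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must equal 1")
        if np.any(np.diff(surv) > 0) or np.any(surv <= 0):
            raise ValueError("survival must be positive and non-increasing")
        if ages[-1] < 110 or surv[ages >= 110][0] >= 1e-3:
            raise ValueError("life table must extend to age 110 with S(110) < 1e-3")
        object.__setattr__(self, "_log_s", np.log(surv))

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def log_survival(self, age) -> np.ndarray:
        age = np.clip(age, 0.0, self.max_age)
        return np.interp(age, self.ages, self._log_s)

    def survival_at(self, age) -> np.ndarray:
        """S(age), log-linearly interpolated; flat beyond the last age."""
        return np.exp(self.log_survival(age))

    def quantile_conditional(self, u, current_age: float, rr: float = 1.0):
        """Age a solving [S(a)/S(current)]**rr = u (inverse-transform sampling).

        ``u`` may be a scalar or array of conditional survival probabilities
        in (0, 1).  Draws falling beyond the table are clamped to the last
        age (death by 110 is certain to within S(110) < 1e-3).
        """
        if rr < 0:
            raise ValueError("relative-risk multiplier must be >= 0")
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u > 1)):
            raise ValueError("u must lie in (0, 1]")
        if not 0 <= current_age <= self.max_age:
            raise ValueError("current_age outside life-table range")
        log_c = self.log_survival(current_age)
        if rr == 0:
            return np.full_like(u, self.max_age) if u.ndim else self.max_age
        target = log_c + np.log(u) / rr  # target log S(a)
        # -log S is increasing in age -> invert with interp
        neg_log = -self._log_s
        ages = np.interp(-target, neg_log, self.ages)
        ages = np.maximum(ages, current_age)
        return ages if u.ndim else float(ages)


def sample_other_cause_death(
    life_table: LifeTable, rr_mortality: float, current_age: float, rng: Generator
):
    """Sample an other-cause death age conditional on survival to current_age.

    The conditional survival is scaled as S*(a|c) = [S(a)/S(c)]**rr, i.e. a
    proportional-hazards scaling of the life table; rr=1 reproduces the
    unscaled table.
    """
    if rr_mortality < 0:
        raise ValueError("relative-risk multiplier must be >= 0")
    u = rng.random()
    while u == 0.0:  # pragma: no cover - probability ~1e-16
        u = rng.random()
    return life_table.quantile_conditional(u, current_age, rr_mortality)


@dataclass(frozen=True)
class DiseaseParams:
    """Parameters of one precursor->preclinical->clinical disease process.

    onset_rates gives the piecewise-constant annual hazard of a *new*
    precursor lesion on [a, a+1) for integer a = 0..110 (per person-year).
    Each lesion walks through ``precursor_states`` with exponential dwell
    times; on leaving state k it becomes preclinical cancer with probability
    p_malignant[k], otherwise it advances to state k+1 (or stalls benignly
    in the last state).  Preclinical cancer turns clinical after an
    exponential sojourn; a clinical stage and a stage-specific exponential
    survival time are then drawn.
    """

    name: str
    precursor_states: tuple[str, ...]
    onset_rates: np.ndarray
    dwell_means: tuple[float, ...]
    p_malignant: tuple[float, ...]
    sojourn_mean: float
    stage_distribution: tuple[float, ...]
    cancer_survival_means: tuple[float, ...]
    screen_stage_shift: tuple[float, ...]

    def __post_init__(self):
        rates = np.asarray(self.onset_rates, dtype=float)
        object.__setattr__(self, "onset_rates", rates)
        if rates.ndim != 1 or len(rates) < 111:
            raise ValueError("onset_rates must cover integer ages 0..110")
        if np.any(rates < 0):
            raise ValueError("onset rates must be >= 0")
        k = len(self.precursor_states)
        if not (len(self.dwell_means) == len(self.p_malignant) == k):
            raise ValueError("dwell_means and p_malignant must match precursor_states")
        if any(m <= 0 for m in self.dwell_means) or self.sojourn_mean <= 0:
            raise ValueError("dwell and sojourn means must be > 0")
        if any(not 0 <= p <= 1 for p in self.p_malignant):
            raise ValueError("p_malignant entries must lie in [0, 1]")
        for dist in (self.stage_distribution, self.screen_stage_shift):
            if abs(sum(dist) - 1.0) > 1e-9 or any(p < 0 for p in dist):
                raise ValueError("stage distributions must be non-negative and sum to 1")
        if len(self.cancer_survival_means) != len(self.stage_distribution):
            raise ValueError("one survival mean per stage required")
        # cumulative onset hazard on integer grid, for NHPP inversion
        cum = np.concatenate([[0.0], np.cumsum(rates)])
        object.__setattr__(self, "_cum_hazard", cum)

    def cumulative_onset_hazard(self, age) -> np.ndarray:
        grid = np.arange(len(self._cum_hazard), dtype=float)
        return np.interp(age, grid, self._cum_hazard)

    def inverse_onset_hazard(self, h) -> np.ndarray:
        """Smallest age with cumulative onset hazard h (inf if beyond table)."""
        grid = np.arange(len(self._cum_hazard), dtype=float)
        total = self._cum_hazard[-1]
        h = np.asarray(h, dtype=float)
        out = np.interp(h, self._cum_hazard, grid)
        out = np.where(h >= total, np.inf, out)
        return out if h.ndim else float(out)


@dataclass
class Lesion:
    """Latent path of a single lesion, simulated to the age horizon.

    Ages past the person's death are counterfactual; they are kept so that
    screening can cancel or reveal them without re-simulating.
    """

    onset_age: float
    state_entry_ages: tuple[float, ...]  # entry age per occupied precursor state
    preclinical_age: float | None
    clinical_age: float | None
    stage: int | None
    cancer_death_age: float | None
    stalled: bool  # never left its last precursor state

    def state_at(self, age: float) -> tuple[str, int | None]:
        """Compartment occupied at ``age``: none/precursor/preclinical/clinical."""
        if age < self.onset_age:
            return ("none", None)
        if self.clinical_age is not None and age >= self.clinical_age:
            return ("clinical", None)
        if self.preclinical_age is not None and age >= self.preclinical_age:
            return ("preclinical", None)
        k = int(np.searchsorted(np.asarray(self.state_entry_ages), age, side="right")) - 1
        return ("precursor", max(k, 0))


def resolve_death(lesions: Sequence[Lesion], other_cause_death_age: float):
    """First-passage resolution of competing cancer deaths vs other causes.

    Scans lesions in order of clinical onset; a lesion's cancer death counts
    only if its clinical onset precedes the death age current at that point.
    Returns (cancer_death_age or None, observed_death_age).
    """
    death = other_cause_death_age
    cancer_death = None
    clinical = sorted(
        (l for l in lesions if l.clinical_age is not None), key=lambda l: l.clinical_age
    )
    for les in clinical:
        if les.clinical_age >= death:
            break
        if les.cancer_death_age is not None and les.cancer_death_age < death:
            death = les.cancer_death_age
            cancer_death = death
    return cancer_death, death


@dataclass
class PersonHistory:
    """Dated event record of one simulated life.

    ``lesions`` holds the latent lesion paths up to the age horizon;
    observed quantities (diagnoses, death age and cause) are resolved via
    :func:`resolve_death` and exposed as attributes/properties so that no
    *observed* event postdates the observed death.
    """

    person_id: int
    entry_age: float
    other_cause_death_age: float
    lesions: list[Lesion] = field(default_factory=list)
    cancer_death_age: float | None = None
    observed_death_age: float = 0.0

    def __post_init__(self):
        self.cancer_death_age, self.observed_death_age = resolve_death(
            self.lesions, self.other_cause_death_age
        )

    @property
    def first_lesion_age(self) -> float | None:
        ages = [l.onset_age for l in self.lesions if l.onset_age < self.observed_death_age]
        return min(ages) if ages else None

    @property
    def clinical_diagnoses(self) -> list[Lesion]:
        """Lesions clinically diagnosed during life, in diagnosis order."""
        out = [
            l
            for l in self.lesions
            if l.clinical_age is not None and l.clinical_age < self.observed_death_age
        ]
        return sorted(out, key=lambda l: l.clinical_age)

    @property
    def died_of_cancer(self) -> bool:
        return self.cancer_death_age is not None


def _draw_stage(u: float, dist: Sequence[float]) -> int:
    c = 0.0
    for i, p in enumerate(dist):
        c += p
        if u < c:
            return i
    return len(dist) - 1


def _sample_lesion(params: DiseaseParams, onset: float, rng: Generator) -> Lesion:
    entries = [onset]
    t = onset
    for k in range(len(params.precursor_states)):
        t += rng.exponential(params.dwell_means[k])
        if rng.random() < params.p_malignant[k]:
            preclinical = t
            clinical = preclinical + rng.exponential(params.sojourn_mean)
            stage = _draw_stage(rng.random(), params.stage_distribution)
            death = clinical + rng.exponential(params.cancer_survival_means[stage])
            return Lesion(onset, tuple(entries), preclinical, clinical, stage, death, False)
        if k + 1 < len(params.precursor_states):
            entries.append(t)
    return Lesion(onset, tuple(entries), None, None, None, None, True)


def _sample_lesions(params: DiseaseParams, horizon: float, rng: Generator) -> list[Lesion]:
    """Non-homogeneous Poisson onsets on [0, horizon] via cumulative-hazard inversion."""
    lesions = []
    h = params.cumulative_onset_hazard(0.0)
    while True:
        h += rng.exponential(1.0)
        onset = params.inverse_onset_hazard(h)
        if not np.isfinite(onset) or onset >= horizon:
            break
        lesions.append(_sample_lesion(params, onset, rng))
    return lesions


def simulate_person(
    disease_params: DiseaseParams,
    life_table: LifeTable,
    rng: Generator,
    *,
    entry_age: float = 40.0,
    rr_mortality: float = 1.0,
    rr_onset_rule: str = "from_first_lesion",
    condition_cancer_free: bool = True,
    person_id: int = 0,
    max_attempts: int = 1000,
) -> PersonHistory:
    """Simulate one life history, conditional on being alive at entry.

    Other-cause death is drawn at entry from the life table; if
    ``rr_mortality`` != 1 the residual survival beyond the relevant onset
    age (first lesion, or entry under the ``lifelong`` rule) is re-scaled
    with the proportional-hazards exponent, re-using the baseline draw's
    conditional quantile so that rr=1 reproduces the baseline draw exactly
    (common random numbers across rr values).

    With ``condition_cancer_free`` (the default) persons with a clinical
    diagnosis before entry are redrawn, emulating recruitment of a cohort
    without diagnosed cancer.
    """
    if rr_mortality < 0:
        raise ValueError("relative-risk multiplier must be >= 0")
    if rr_onset_rule not in ("from_first_lesion", "lifelong"):
        raise ValueError(f"unknown rr_onset_rule: {rr_onset_rule!r}")
    horizon = life_table.max_age
    for _ in range(max_attempts):
        ocd0 = sample_other_cause_death(life_table, 1.0, entry_age, rng)
        lesions = _sample_lesions(disease_params, horizon, rng)
        if condition_cancer_free and any(
            l.clinical_age is not None and l.clinical_age < entry_age for l in lesions
        ):
            continue
        break
    else:  # pragma: no cover
        raise RuntimeError("failed to draw a cancer-free entrant")

    ocd = ocd0
    if rr_mortality != 1.0:
        onsets = [l.onset_age for l in lesions]
        first = min(onsets) if onsets else None
        if rr_onset_rule == "lifelong":
            scale_from = entry_age
        else:
            scale_from = max(first, entry_age) if first is not None else None
        if scale_from is not None and scale_from < ocd0:
            # conditional survival reached at the baseline draw, then re-scaled
            v = np.exp(life_table.log_survival(ocd0) - life_table.log_survival(scale_from))
            v = min(max(v, 1e-300), 1.0)
            ocd = life_table.quantile_conditional(v, scale_from, rr_mortality)

    lesions = [l for l in lesions if l.onset_age < ocd]
    return PersonHistory(person_id, entry_age, float(ocd), lesions)


def simulate_cohort(
    n: int,
    disease_params: DiseaseParams,
    life_table: LifeTable,
    rr_mortality: float = 1.0,
    seed: int = 0,
    *,
    entry_age: float = 40.0,
    rr_onset_rule: str = "from_first_lesion",
    condition_cancer_free: bool = True,
) -> list[PersonHistory]:
    """Simulate ``n`` independent persons entering the cohort at ``entry_age``.

    Reproducible given ``seed``; person ``i`` uses the dedicated stream
    ``person_rng(seed, i, PURPOSE_NATURAL_HISTORY)`` so cohorts are pairable
    across strategies and rr values (common random numbers).
    """
    if n <= 0:
        raise ValueError("cohort size must be >= 1")
    cohort = []
    for i in range(n):
        rng = person_rng(seed, i, PURPOSE_NATURAL_HISTORY)
        cohort.append(
            simulate_person(
                disease_params,
                life_table,
                rng,
                entry_age=entry_age,
                rr_mortality=rr_mortality,
                rr_onset_rule=rr_onset_rule,
                condition_cancer_free=condition_cancer_free,
                person_id=i,
            )
        )
    return cohort
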