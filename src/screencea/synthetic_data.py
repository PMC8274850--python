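"""Synthetic generators for every input the screening CEA pipeline needs.

The real analyses behind this package rest on inputs that are either survey
estimates (per-capita health expenditures by age, utility-by-age), national
life tables, or calibrated natural-history parameters that are not public.
This module generates statistical stand-ins with the same structure:

* a Gompertz–Makeham life table with life expectancy near 78 years,
* MEPS-like expenditure observations (exponential truth curve + noise,
  population-size weights),
* utility-by-age observations (linear decreasing truth, clipped to (0, 1]),
* disease natural-history parameters for a colorectal-cancer-like process
  (small/medium/large adenoma) and an esophageal-adenocarcinoma-like
  process (Barrett's esophagus with no/low/high-grade dysplasia),
* the grid of screening strategies evaluated (20 colonoscopy start/stop/
  interval combinations; two once-only esophageal strategies).

Every generator is a pure function of (config, seed): sub-streams are
derived from the master seed with fixed per-generator offsets, so adding a
generator never perturbs the others.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from numpy.random import Generator, PCG64, SeedSequence

from .natural_history import DiseaseParams, LifeTable
from .population_inputs import AgeValueSeries
from .screening import Strategy, SurveillanceRule, TestCharacteristics

__all__ = [
    "SyntheticConfig",
    "make_life_table",
    "make_cost_observations",
    "make_utility_observations",
    "default_strategy_grid",
    "crc_like_params",
    "eac_like_params",
    "CRC_STRATEGY_GRID",
    "write_life_table_csv",
    "write_series_csv",
    "write_strategy_grid_csv",
    "write_config_yaml",
]

# fixed sub-stream offsets per generator
_STREAM_COST = 1
_STREAM_UTILITY = 2

OBS_AGE_MIN = 18
OBS_AGE_MAX = 85


def _truth_value(form: str, params, ages):
    ages = np.asarray(ages, dtype=float)
    p = list(params)
    if form == "exponential":
        return p[0] * np.exp(p[1] * ages)
    if form == "linear":
        return p[0] + p[1] * ages
    if form == "quadratic":
        return p[0] + p[1] * ages + p[2] * ages**2
    raise ValueError(f"unknown truth-curve form: {form!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic input generators.

    Defaults encode the study conditions: US-like longevity (life expectancy
    at birth ~78 y), per-capita annual health expenditures rising
    exponentially from ~$1,100 at age 20 to ~$15,000 at age 85, utility
    declining linearly from 0.92 at age 18 to ~0.74 at 85, and population
    weights that thin out at older ages.
    """

    seed: int = 12345
    cohort_size: int = 10_000
    # (makeham background rate, gompertz scale, gompertz shape), per year
    gompertz_params: tuple[float, float, float] = (5.0e-4, 2.8e-5, 0.095)
    # (form, params, observation noise sd)
    cost_curve_truth: tuple = ("exponential", (500.0, 0.04), 400.0)
    utility_curve_truth: tuple = ("linear", (0.9686, -0.0027), 0.015)

    def __post_init__(self):
        lam, scale, shape = self.gompertz_params
        if lam < 0 or scale <= 0 or shape <= 0:
            raise ValueError("Gompertz-Makeham rate must be >=0, scale and shape > 0")
        if self.cost_curve_truth[2] < 0 or self.utility_curve_truth[2] < 0:
            raise ValueError("observation noise sd must be >= 0")
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")

    def population_weights(self, ages) -> np.ndarray:
        """US-like age-specific population sizes (arbitrary units, positive)."""
        ages = np.asarray(ages, dtype=float)
        return 4.0e6 * np.exp(-0.018 * np.maximum(ages - 50.0, 0.0))

    def _rng(self, offset: int) -> Generator:
        return Generator(PCG64(SeedSequence(entropy=(int(self.seed), int(offset)))))


def make_life_table(config: SyntheticConfig) -> LifeTable:
    """Gompertz–Makeham life table on integer ages 0..110.

    S(a) = exp(-lam*a - (scale/shape)*(exp(shape*a) - 1)).
    """
    lam, scale, shape = config.gompertz_params
    ages = np.arange(111, dtype=float)
    cum_hazard = lam * ages + (scale / shape) * (np.exp(shape * ages) - 1.0)
    return LifeTable(ages=ages, survival=np.exp(-cum_hazard))


def gompertz_makeham_survival(ages, makeham: float, scale: float, shape: float):
    """Closed-form Gompertz–Makeham survival (used by tests as an oracle)."""
    ages = np.asarray(ages, dtype=float)
    return np.exp(-makeham * ages - (scale / shape) * (np.exp(shape * ages) - 1.0))


def _make_observations(config, truth, stream, clip_unit: bool) -> AgeValueSeries:
    form, params, sd = truth
    ages = np.arange(OBS_AGE_MIN, OBS_AGE_MAX + 1, dtype=float)
    values = _truth_value(form, params, ages)
    if sd > 0:
        values = values + sd * config._rng(stream).standard_normal(len(ages))
    if clip_unit:
        values = np.clip(values, 1e-9, 1.0)
    else:
        values = np.maximum(values, 0.0)
    return AgeValueSeries(ages=ages, values=values, weights=config.population_weights(ages))


def make_cost_observations(config: SyntheticConfig) -> AgeValueSeries:
    """MEPS-like per-capita expenditure observations, one per age 18..85."""
    return _make_observations(config, config.cost_curve_truth, _STREAM_COST, clip_unit=False)


def make_utility_observations(config: SyntheticConfig) -> AgeValueSeries:
    """Utility-by-age observations in (0, 1], one per age 18..85."""
    return _make_observations(config, config.utility_curve_truth, _STREAM_UTILITY, clip_unit=True)


# ---------------------------------------------------------------------------
# disease parameters (synthetic stand-ins with the published state topology)

def _exp_rates(r0: float, growth: float, start_age: float) -> np.ndarray:
    ages = np.arange(111, dtype=float)
    rates = r0 * np.exp(growth * ages)
    rates[ages < start_age] = 0.0
    return rates


def crc_like_params() -> DiseaseParams:
    """Colorectal-cancer-like process: small/medium/large adenoma pathway.

    Onset hazard rises exponentially with age from age 20 (lifetime chance
    of any adenoma ~35-40%); dwell times of several years per adenoma size
    class; most adenomas never progress.
    """
    return DiseaseParams(
        name="crc_like",
        precursor_states=("small_adenoma", "medium_adenoma", "large_adenoma"),
        onset_rates=_exp_rates(6.0e-4, 0.04, start_age=20.0),
        dwell_means=(8.0, 6.0, 5.0),
        p_malignant=(0.01, 0.04, 0.20),
        sojourn_mean=4.0,
        stage_distribution=(0.20, 0.30, 0.30, 0.20),
        cancer_survival_means=(25.0, 12.0, 5.0, 1.5),
        screen_stage_shift=(0.50, 0.30, 0.15, 0.05),
    )


def eac_like_params() -> DiseaseParams:
    """Esophageal-adenocarcinoma-like process in a GERD population.

    Barrett's esophagus onset from age 25; dysplasia grades progress slowly
    and rarely; preclinical sojourn shorter and clinical survival poorer
    than the colorectal process.
    """
    return DiseaseParams(
        name="eac_like",
        precursor_states=("be_no_dysplasia", "be_low_grade", "be_high_grade"),
        onset_rates=_exp_rates(1.2e-3, 0.015, start_age=25.0),
        dwell_means=(12.0, 5.0, 3.0),
        p_malignant=(0.02, 0.08, 0.35),
        sojourn_mean=3.0,
        stage_distribution=(0.15, 0.25, 0.30, 0.30),
        cancer_survival_means=(12.0, 6.0, 2.5, 0.8),
        screen_stage_shift=(0.50, 0.30, 0.15, 0.05),
    )


# ---------------------------------------------------------------------------
# screening strategy grids

def colonoscopy_test() -> TestCharacteristics:
    return TestCharacteristics(
        sensitivity={
            "small_adenoma": 0.75,
            "medium_adenoma": 0.85,
            "large_adenoma": 0.95,
            "preclinical": 0.95,
        },
        specificity=0.90,
        cost=1000.0,
        complication_prob=0.002,
        complication_cost=5000.0,
        removal_cost=500.0,
        disutility=0.005,
    )


def endoscopy_test() -> TestCharacteristics:
    return TestCharacteristics(
        sensitivity={
            "be_no_dysplasia": 0.85,
            "be_low_grade": 0.85,
            "be_high_grade": 0.90,
            "preclinical": 0.95,
        },
        specificity=0.95,
        cost=800.0,
        complication_prob=0.001,
        complication_cost=4000.0,
        removal_cost=2500.0,  # endoscopic therapy of dysplastic segments
        disutility=0.004,
    )


def cytosponge_test() -> TestCharacteristics:
    return TestCharacteristics(
        sensitivity={
            "be_no_dysplasia": 0.75,
            "be_low_grade": 0.80,
            "be_high_grade": 0.85,
            "preclinical": 0.85,
        },
        specificity=0.92,
        cost=250.0,
        disutility=0.001,
        triage=endoscopy_test(),
    )


# the 20 colonoscopy (start, stop, interval) rows of the evaluated grid
CRC_STRATEGY_GRID: tuple[tuple[int, int, int], ...] = (
    (55, 75, 15), (55, 85, 15), (55, 75, 10), (55, 85, 10),
    (55, 75, 5), (55, 80, 5), (55, 85, 5),
    (50, 75, 15), (50, 80, 15), (50, 75, 10), (50, 80, 10),
    (50, 75, 5), (50, 80, 5), (50, 85, 5),
    (45, 75, 15), (45, 75, 10), (45, 85, 10),
    (45, 75, 5), (45, 80, 5), (45, 85, 5),
)


def crc_surveillance() -> SurveillanceRule:
    return SurveillanceRule(
        high_risk_interval=3.0,
        low_risk_interval=5.0,
        high_risk_states=("large_adenoma",),
    )


def eac_surveillance() -> SurveillanceRule:
    return SurveillanceRule(
        high_risk_interval=3.0,
        low_risk_interval=5.0,
        high_risk_states=("be_high_grade",),
    )


def no_screening() -> Strategy:
    return Strategy(label="No screening", modality="none", start_age=0.0, stop_age=0.0)


def default_strategy_grid(disease: str) -> list[Strategy]:
    """The evaluated screening strategies for a disease tag.

    ``crc_like``: the 20 colonoscopy (start, stop, interval) combinations;
    ``eac_like``: once-only endoscopy at 60 and once-only cytosponge at 60
    with endoscopic follow-up of positives.
    """
    if disease == "crc_like":
        return [
            Strategy(
                label=f"Colonoscopy, {start}-{stop}, {interval}",
                modality="colonoscopy",
                start_age=float(start),
                stop_age=float(stop),
                interval=float(interval),
                test=colonoscopy_test(),
                surveillance=crc_surveillance(),
            )
            for start, stop, interval in CRC_STRATEGY_GRID
        ]
    if disease == "eac_like":
        return [
            Strategy(
                label="Cytosponge, 60",
                modality="cytosponge_then_endoscopy",
                start_age=60.0,
                stop_age=60.0,
                interval=None,
                test=cytosponge_test(),
                surveillance=eac_surveillance(),
            ),
            Strategy(
                label="Endoscopy, 60",
                modality="endoscopy",
                start_age=60.0,
                stop_age=60.0,
                interval=None,
                test=endoscopy_test(),
                surveillance=eac_surveillance(),
            ),
        ]
    raise ValueError(f"unknown disease tag: {disease!r}")


# ---------------------------------------------------------------------------
# writers

def write_life_table_csv(table: LifeTable, path) -> None:
    import pandas as pd

    pd.DataFrame({"age": table.ages, "survival": table.survival}).to_csv(path, index=False)


def write_series_csv(series: AgeValueSeries, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"age": series.ages, "value": series.values, "weight": series.weights}
    ).to_csv(path, index=False)


def write_strategy_grid_csv(strategies: list[Strategy], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "label": [s.label for s in strategies],
            "modality": [s.modality for s in strategies],
            "start_age": [s.start_age for s in strategies],
            "stop_age": [s.stop_age for s in strategies],
            "interval": [s.interval if s.interval is not None else "once_only" for s in strategies],
        }
    ).to_csv(path, index=False)


def write_config_yaml(config: SyntheticConfig, path) -> None:
    data = asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
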