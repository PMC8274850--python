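"""Weighted nonlinear least-squares age curves for expenditures and utility.

Observed (age, value, weight) triples — per-capita health expenditures or
utilities, weighted by age-specific population size — are condensed into a
continuous parametric curve of age, minimizing

    SSE(theta) = sum_i w_i * (value_i - f(age_i; theta))^2.

Fitted curves are evaluated with flat extrapolation outside the observed
age range (preventing explosive exponential costs at very old ages) and,
for utility curves, clipping to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["AgeValueSeries", "AgeCurve", "FitError", "fit_age_curve", "evaluate"]


class FitError(RuntimeError):
    """Raised when no optimizer start converges."""


@dataclass(frozen=True)
class AgeValueSeries:
    """Weighted observations of some quantity by age (weights > 0, ages unique)."""

    ages: np.ndarray
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        for name, arr in (("ages", ages), ("values", values), ("weights", weights)):
            object.__setattr__(self, name, arr)
        if not (len(ages) == len(values) == len(weights)):
            raise ValueError("ages, values and weights must have equal length")
        if len(np.unique(ages)) != len(ages):
            raise ValueError("ages must be unique")
        if np.any(weights <= 0):
            raise ValueError("weights must be > 0")

    def __len__(self):
        return len(self.ages)


def _f_exponential(ages, p):
    return p[0] * np.exp(p[1] * ages)


def _f_linear(ages, p):
    return p[0] + p[1] * ages


def _f_quadratic(ages, p):
    return p[0] + p[1] * ages + p[2] * ages**2


def _f_logistic(ages, p):
    # L / (1 + exp(-k (a - x0))): monotone sigmoid in age
    return p[0] / (1.0 + np.exp(-p[2] * (ages - p[1])))


def _init_exponential(s: AgeValueSeries):
    pos = s.values > 0
    if pos.sum() >= 2:
        b, loga = np.polyfit(s.ages[pos], np.log(s.values[pos]), 1)
        return [np.exp(loga), b]
    return [max(s.values.mean(), 1e-6), 0.01]


def _init_linear(s: AgeValueSeries):
    b, a = np.polyfit(s.ages, s.values, 1)
    return [a, b]


def _init_quadratic(s: AgeValueSeries):
    c, b, a = np.polyfit(s.ages, s.values, 2)
    return [a, b, c]


def _init_logistic(s: AgeValueSeries):
    return [max(s.values.max(), 1e-6), float(np.median(s.ages)), 0.05]


_FORMS = {
    "exponential": (_f_exponential, 2, _init_exponential),
    "linear": (_f_linear, 2, _init_linear),
    "quadratic": (_f_quadratic, 3, _init_quadratic),
    "logistic": (_f_logistic, 3, _init_logistic),
}

# deterministic multiplicative perturbations of the moment-based start
_START_FACTORS = (1.0, 0.8, 1.25, 0.5, 2.0)


@dataclass(frozen=True)
class AgeCurve:
    """A fitted parametric function of age.

    ``domain`` is the observed age range; evaluation outside it is flat
    (value at the nearest domain edge).  Curves flagged ``clip_unit`` (the
    utility curves) are clipped to [0, 1] on evaluation.
    """

    form: str
    parameters: tuple[float, ...]
    domain: tuple[float, float]
    clip_unit: bool = False
    sse: float = float("nan")

    def __call__(self, age):
        return evaluate(self, age)


def fit_age_curve(series: AgeValueSeries, form: str, clip_unit: bool | None = None) -> AgeCurve:
    """Weighted nonlinear least-squares fit of ``form`` to the series.

    Multi-start local least squares (the moment-based initial guess plus
    deterministic perturbations); the best converged start wins.  Weighted
    residuals are sqrt(w_i) * (value_i - f(age_i)), so the objective is the
    weighted SSE.  Raises :class:`FitError` if no start converges.
    """
    if form not in _FORMS:
        raise ValueError(f"unsupported curve form: {form!r}")
    f, n_par, init = _FORMS[form]
    if len(series) < n_par:
        raise ValueError(f"need at least {n_par} observations for form {form!r}")
    sw = np.sqrt(series.weights)

    def residuals(p):
        return sw * (series.values - f(series.ages, p))

    p0 = np.asarray(init(series), dtype=float)
    best = None
    for fac in _START_FACTORS:
        start = p0 * fac
        try:
            res = least_squares(residuals, start, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if not res.success:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[1] * (1 - 1e-10):
            best = (res.x, sse)
    if best is None:
        raise FitError(f"weighted least squares failed to converge for form {form!r}")
    params, sse = best
    if clip_unit is None:
        clip_unit = bool(np.all(series.values <= 1.0))
    return AgeCurve(
        form=form,
        parameters=tuple(float(x) for x in params),
        domain=(float(series.ages.min()), float(series.ages.max())),
        clip_unit=clip_unit,
        sse=sse,
    )


def evaluate(curve: AgeCurve, age):
    """Evaluate the curve with flat extrapolation and optional [0,1] clipping."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    clamped = np.clip(age, curve.domain[0], curve.domain[1])
    f = _FORMS[curve.form][0]
    out = f(clamped, np.asarray(curve.parameters))
    if curve.clip_unit:
        out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
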