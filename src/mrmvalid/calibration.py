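"""Weighted calibration-curve fitting, back-calculation and model selection.

Calibration curves relate nominal concentration ``x`` to the measured
analyte/IS peak-area ratio ``y``.  Peak-area noise in electrospray LC-MS/MS
is close to proportional, so fits are weighted least squares with weights
1, 1/x or 1/x², minimizing ``sum w_i (y_i - f(x_i))**2`` for a straight line
``a + b x`` or a parabola ``a + b x + c x²``.

Goodness of fit is judged on the concentration scale: each calibrator is
back-calculated through the fitted curve and its percent relative error
(%RE) versus nominal recorded.  Models are compared by the sum of absolute
%RE values and by an Akaike information criterion on the sum of squared
relative errors,

    AIC = n * ln(SSR) + 2 M,   SSR = sum((%RE_i / 100)**2),

with ``n`` the number of calibrators and ``M`` the number of regression
coefficients (2 linear, 3 quadratic; the weighting choice adds no
parameter).  The smallest AIC wins; ties go to the model with fewer
coefficients, then to the simpler weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationLevel",
    "CalibrationFit",
    "fit_curve",
    "back_calculate",
    "aic",
    "select_model",
    "MODELS",
    "WEIGHTINGS",
]

MODELS = ("linear", "quadratic")
WEIGHTINGS = ("none", "1/x", "1/x^2")

#: Tie-break order for weightings: simpler first.
_WEIGHT_RANK = {w: i for i, w in enumerate(WEIGHTINGS)}


@dataclass(frozen=True)
class CalibrationLevel:
    """One calibrator injection: nominal concentration and peak areas."""

    nominal_conc: float
    analyte_area: float
    is_area: float

    def __post_init__(self) -> None:
        if self.nominal_conc <= 0:
            raise ValueError("calibrator nominal concentration must be positive")
        if self.analyte_area < 0 or self.is_area <= 0:
            raise ValueError("areas must be non-negative and IS area positive")

    @property
    def response_ratio(self) -> float:
        return self.analyte_area / self.is_area


@dataclass
class CalibrationFit:
    """A fitted calibration model plus its back-calculation diagnostics."""

    model: str
    weighting: str
    coefficients: Tuple[float, ...]  # (a, b) or (a, b, c)
    n_levels: int
    nominal_concs: Tuple[float, ...]
    re_pct_per_level: Tuple[float, ...]
    re_sum: float
    ssr_rel: float
    aic: float
    r: float
    x_max: float

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    @property
    def slope(self) -> float:
        return self.coefficients[1]

    @property
    def curvature(self) -> Optional[float]:
        return self.coefficients[2] if len(self.coefficients) == 3 else None

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        y = self.coefficients[0] + self.coefficients[1] * x
        if len(self.coefficients) == 3:
            y = y + self.coefficients[2] * x**2
        return y if y.ndim else float(y)


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if np.any(x <= 0):
        raise ValueError(f"weighting {weighting!r} requires positive concentrations")
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x^2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}")


def aic(n: int, ssr: float, n_params: int) -> float:
    """``n * ln(SSR) + 2M``; -inf for a numerically perfect fit (SSR == 0)."""
    if n < 1:
        raise ValueError("need at least one calibrator")
    if ssr < 0:
        raise ValueError("SSR cannot be negative")
    if ssr == 0:
        return -math.inf
    return n * math.log(ssr) + 2 * n_params


def fit_curve(
    levels: Sequence[CalibrationLevel],
    model: str = "linear",
    weighting: str = "1/x",
    mask: Optional[Sequence[bool]] = None,
) -> CalibrationFit:
    """Weighted least-squares fit of a calibration model to response ratios.

    Parameters
    ----------
    levels:
        Calibrator injections; at least 3 for linear and 4 for quadratic,
        with at least two distinct concentrations (three for quadratic).
    mask:
        Optional per-level keep flags for explicit calibrator exclusion;
        excluded levels take no part in the fit or its diagnostics.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if mask is not None:
        if len(mask) != len(levels):
            raise ValueError("mask length must match number of levels")
        levels = [lev for lev, keep in zip(levels, mask) if keep]
    n_params = 2 if model == "linear" else 3
    min_levels = 3 if model == "linear" else 4
    if len(levels) < min_levels:
        raise ValueError(f"{model} fit needs at least {min_levels} calibrators")
    x = np.array([lev.nominal_conc for lev in levels], dtype=float)
    y = np.array([lev.response_ratio for lev in levels], dtype=float)
    if len(np.unique(x)) < n_params:
        raise ValueError("design is singular: too few distinct concentrations")
    w = _weights(x, weighting)

    design = np.vander(x, n_params, increasing=True)  # columns 1, x, (x^2)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    coefficients = tuple(float(c) for c in coef)

    fitted = design @ coef
    fit = CalibrationFit(
        model=model,
        weighting=weighting,
        coefficients=coefficients,
        n_levels=len(levels),
        nominal_concs=tuple(x),
        re_pct_per_level=(),
        re_sum=math.nan,
        ssr_rel=math.nan,
        aic=math.nan,
        r=_weighted_pearson(y, fitted, w),
        x_max=float(x.max()),
    )
    re_pct = []
    for xi, yi in zip(x, y):
        back = back_calculate(fit, yi)
        re_pct.append(100.0 * (back - xi) / xi if not math.isnan(back) else math.nan)
    fit.re_pct_per_level = tuple(re_pct)
    finite = [v for v in re_pct if not math.isnan(v)]
    fit.re_sum = float(sum(abs(v) for v in finite))
    fit.ssr_rel = float(sum((v / 100.0) ** 2 for v in finite))
    fit.aic = aic(len(levels), fit.ssr_rel, n_params)
    return fit


def _weighted_pearson(y: np.ndarray, fitted: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    my, mf = (w * y).sum() / wsum, (w * fitted).sum() / wsum
    cov = (w * (y - my) * (fitted - mf)).sum()
    vy = (w * (y - my) ** 2).sum()
    vf = (w * (fitted - mf) ** 2).sum()
    if vy <= 0 or vf <= 0:
        return math.nan
    return float(cov / math.sqrt(vy * vf))


def back_calculate(fit: CalibrationFit, response_ratio: float) -> float:
    """Invert the calibration curve; NaN flags a non-quantifiable response.

    Linear: ``x = (y - a) / b``.  Quadratic: solve ``c x² + b x + a = y`` and
    return the real root inside ``[0, 2 * x_max]`` (covering the validated
    dilution workflow); with two admissible roots, the one nearer the
    linear-term estimate ``(y - a) / b`` wins.  No real or admissible root
    returns ``nan`` rather than raising, so batch back-calculation of
    pathological samples survives.
    """
    a, b = fit.coefficients[0], fit.coefficients[1]
    if fit.model == "linear" or not fit.coefficients[2:] or fit.coefficients[2] == 0:
        if b == 0:
            return math.nan
        return (response_ratio - a) / b
    c = fit.coefficients[2]
    disc = b * b - 4 * c * (a - response_ratio)
    if disc < 0:
        return math.nan
    sq = math.sqrt(disc)
    roots = [(-b + sq) / (2 * c), (-b - sq) / (2 * c)]
    upper = 2.0 * fit.x_max
    admissible = [r for r in roots if -1e-9 * fit.x_max <= r <= upper]
    if not admissible:
        return math.nan
    if len(admissible) == 1:
        return float(max(admissible[0], 0.0))
    linear_guess = (response_ratio - a) / b if b != 0 else 0.0
    best = min(admissible, key=lambda r: abs(r - linear_guess))
    return float(max(best, 0.0))


def select_model(
    levels: Sequence[CalibrationLevel],
    candidates: Iterable[Tuple[str, str]] = (
        ("linear", "1/x"),
        ("linear", "1/x^2"),
        ("quadratic", "1/x"),
        ("quadratic", "1/x^2"),
    ),
    mask: Optional[Sequence[bool]] = None,
) -> Tuple[CalibrationFit, pd.DataFrame]:
    """Fit every candidate (model, weighting) pair and pick the smallest AIC.

    Returns the winning fit and a comparison table with one row per
    candidate (columns ``model``, ``weighting``, ``re_sum``, ``aic``, ``r``,
    ``selected``).  Candidates whose fit fails (e.g. too few levels for a
    quadratic) appear in the table with NaN statistics.  AIC ties break
    toward fewer coefficients, then simpler weighting.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate models supplied")
    rows = []
    fits: List[Optional[CalibrationFit]] = []
    errors = []
    for model, weighting in candidates:
        try:
            fit = fit_curve(levels, model, weighting, mask=mask)
            fits.append(fit)
            rows.append(
                {"model": model, "weighting": weighting, "re_sum": fit.re_sum,
                 "aic": fit.aic, "r": fit.r}
            )
        except ValueError as exc:
            fits.append(None)
            errors.append(f"{model}/{weighting}: {exc}")
            rows.append(
                {"model": model, "weighting": weighting, "re_sum": math.nan,
                 "aic": math.nan, "r": math.nan}
            )
    successful = [(i, f) for i, f in enumerate(fits) if f is not None]
    if not successful:
        raise ValueError("all candidate fits failed: " + "; ".join(errors))

    def rank(item: Tuple[int, CalibrationFit]):
        _, f = item
        return (f.aic, len(f.coefficients), _WEIGHT_RANK[f.weighting])

    best_idx, best = min(successful, key=rank)
    table = pd.DataFrame(rows)
    table["selected"] = [i == best_idx for i in range(len(rows))]
    return best, table
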