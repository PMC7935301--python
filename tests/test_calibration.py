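"""Weighted calibration fitting, back-calculation, AIC model selection."""

import math

import numpy as np
import pytest

from mrmvalid.calibration import (
    CalibrationLevel,
    aic,
    back_calculate,
    fit_curve,
    select_model,
)

HCQ_LEVELS = (2, 5, 10, 20, 50, 100, 200, 500, 1000)


def make_levels(x, y, is_area=1e5):
    return [CalibrationLevel(xi, yi * is_area, is_area) for xi, yi in zip(x, y)]


def normal_equation_fit(x, y, w, degree):
    """Independent brute-force weighted LS via explicit normal equations."""
    design = np.vander(np.asarray(x, float), degree + 1, increasing=True)
    W = np.diag(w)
    lhs = design.T @ W @ design
    rhs = design.T @ W @ np.asarray(y, float)
    return np.linalg.solve(lhs, rhs)


def test_noiseless_linear_recovery():
    x = np.array(HCQ_LEVELS, float)
    fit = fit_curve(make_levels(x, 0.002 * x), "linear", "1/x")
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.slope == pytest.approx(0.002, rel=1e-9)
    assert fit.re_sum == pytest.approx(0.0, abs=1e-6)
    assert fit.aic < -100  # SSR at float round-off drives AIC to a huge negative
    assert fit.r == pytest.approx(1.0, abs=1e-9)


def test_noiseless_quadratic_recovery():
    x = np.array(HCQ_LEVELS, float)
    y = 1e-3 * x - 2e-7 * x**2
    fit = fit_curve(make_levels(x, y), "quadratic", "1/x^2")
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.slope == pytest.approx(1e-3, rel=1e-9)
    assert fit.curvature == pytest.approx(-2e-7, rel=1e-9)


@pytest.mark.parametrize("weighting", ["none", "1/x", "1/x^2"])
@pytest.mark.parametrize("model,degree", [("linear", 1), ("quadratic", 2)])
def test_fit_matches_normal_equations(model, degree, weighting):
    """Small-design fits agree with an explicit normal-equation solution."""
    rng = np.random.default_rng(42)
    x = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
    y = 0.01 * x * (1 + rng.normal(0, 0.05, size=5))
    fit = fit_curve(make_levels(x, y), model, weighting)
    if weighting == "none":
        w = np.ones_like(x)
    elif weighting == "1/x":
        w = 1 / x
    else:
        w = 1 / x**2
    expected = normal_equation_fit(x, y, w, degree)
    for got, want in zip(fit.coefficients, expected):
        assert got == pytest.approx(want, rel=1e-9)


def test_back_calculate_linear_algebra():
    fit = fit_curve(make_levels(np.array([1, 10, 1000.0]),
                                0.002 * np.array([1, 10, 1000.0])), "linear", "1/x")
    assert back_calculate(fit, 2.0) == pytest.approx(1000.0, rel=1e-9)


def test_back_calculate_quadratic_round_trip():
    x = np.array(HCQ_LEVELS, float)
    y = 3e-3 * x - 3e-7 * x**2
    fit = fit_curve(make_levels(x, y), "quadratic", "1/x^2")
    for xi, yi in zip(x, y):
        assert back_calculate(fit, yi) == pytest.approx(xi, rel=1e-9)


def test_back_calculate_beyond_saturation_flags_non_quantifiable():
    """A response above a saturating parabola's apex has no admissible root."""
    x = np.array(HCQ_LEVELS, float)
    y = 1e-3 * x - 4e-7 * x**2  # apex at x = 1250, y = 0.625
    fit = fit_curve(make_levels(x, y), "quadratic", "1/x^2")
    assert math.isnan(back_calculate(fit, 0.7))


def test_noiseless_back_calculation_returns_nominals():
    x = np.array(HCQ_LEVELS, float)
    fit = fit_curve(make_levels(x, 0.005 * x + 0.001), "linear", "1/x^2")
    for xi in x:
        assert back_calculate(fit, fit.predict(xi)) == pytest.approx(xi, rel=1e-9)


def test_aic_formula():
    assert aic(9, 1.0, 2) == pytest.approx(4.0)
    assert aic(9, math.e, 3) == pytest.approx(15.0)
    assert aic(5, 0.0, 2) == -math.inf
    with pytest.raises(ValueError):
        aic(9, -1.0, 2)


def test_aic_monotone_in_ssr():
    values = [aic(9, s, 2) for s in (0.01, 0.1, 1.0, 10.0)]
    assert values == sorted(values)


def test_statistics_invariant_to_common_area_rescaling():
    """Response ratios are scale-free, so %RE sum and AIC must be too."""
    rng = np.random.default_rng(7)
    x = np.array(HCQ_LEVELS, float)
    y = 0.002 * x * (1 + rng.normal(0, 0.05, size=len(x)))
    fit1 = fit_curve(make_levels(x, y, is_area=1e5), "linear", "1/x")
    fit2 = fit_curve(make_levels(x, y, is_area=3.7e6), "linear", "1/x")
    assert fit1.re_sum == pytest.approx(fit2.re_sum, rel=1e-9)
    assert fit1.aic == pytest.approx(fit2.aic, rel=1e-9)


def test_inverse_square_weighting_equalizes_relative_residuals():
    """With 1/x² weights, equal relative errors contribute equal loss."""
    x = np.array([2.0, 1000.0])
    # both points 5% above a y = 0.002 x line
    y = 0.002 * x * 1.05
    resid = y - 0.002 * x
    w = 1 / x**2
    losses = w * resid**2
    assert losses[0] == pytest.approx(losses[1], rel=1e-12)


def test_select_model_single_candidate():
    x = np.array(HCQ_LEVELS, float)
    fit, table = select_model(make_levels(x, 0.002 * x), [("linear", "1/x")])
    assert (fit.model, fit.weighting) == ("linear", "1/x")
    assert len(table) == 1 and table["selected"].all()


def test_select_model_parsimony_tie_break():
    """On noiseless linear data both models are perfect; fewer terms win."""
    x = np.array(HCQ_LEVELS, float)
    fit, table = select_model(
        make_levels(x, 0.002 * x),
        [("linear", "1/x"), ("quadratic", "1/x^2")],
    )
    assert fit.model == "linear"
    assert table.loc[table["selected"], "model"].iloc[0] == "linear"


def test_fit_errors():
    x = np.array([5.0, 5.0, 5.0])
    with pytest.raises(ValueError):
        fit_curve(make_levels(x, 0.01 * x), "linear", "1/x")  # singular design
    with pytest.raises(ValueError):
        fit_curve(make_levels(np.array([1.0, 2.0]), np.array([0.1, 0.2])),
                  "linear", "1/x")  # too few levels
    with pytest.raises(ValueError):
        fit_curve(make_levels(np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 4.0])),
                  "linear", "bogus")


def _quadratic_truth_dataset(rng, cv=0.05):
    x = np.array(HCQ_LEVELS, float)
    y = 3e-3 * x - 3e-7 * x**2
    return make_levels(x, y * (1 + rng.normal(0, cv, size=len(x))))


def test_aic_prefers_quadratic_on_curved_truth():
    """Monte-Carlo: quadratic/1/x² beats linear/1/x on saturating data."""
    wins = 0
    selected = 0
    n_trials = 200
    for trial in range(n_trials):
        rng = np.random.default_rng(1000 + trial)
        levels = _quadratic_truth_dataset(rng)
        quad = fit_curve(levels, "quadratic", "1/x^2")
        lin = fit_curve(levels, "linear", "1/x")
        wins += quad.aic < lin.aic
        best, _ = select_model(levels)
        selected += best.model == "quadratic"
    assert wins >= 0.8 * n_trials
    assert selected > n_trials / 2


def test_coefficients_unbiased_over_monte_carlo():
    """Fitted slope on proportional-noise linear data is unbiased (3·SE)."""
    x = np.array(HCQ_LEVELS, float)
    slopes = []
    for trial in range(200):
        rng = np.random.default_rng(5000 + trial)
        y = 0.002 * x * (1 + rng.normal(0, 0.05, size=len(x)))
        slopes.append(fit_curve(make_levels(x, y), "linear", "1/x").slope)
    slopes = np.asarray(slopes)
    se = slopes.std(ddof=1) / math.sqrt(len(slopes))
    assert abs(slopes.mean() - 0.002) < 3 * se


def test_explicit_mask_excludes_calibrator():
    x = np.array([1, 2, 5, 10.0])
    y = 0.01 * x
    y[3] = 0.5  # gross outlier at the top level
    levels = make_levels(x, y)
    biased = fit_curve(levels, "linear", "1/x")
    masked = fit_curve(levels, "linear", "1/x", mask=[True, True, True, False])
    assert masked.n_levels == 3
    assert abs(masked.slope - 0.01) < abs(biased.slope - 0.01)
    assert masked.slope == pytest.approx(0.01, rel=1e-9)
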