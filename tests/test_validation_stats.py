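"""Validation battery: precision/accuracy, dilution, blanks, stability."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmvalid.validation_stats import (
    AcceptanceResult,
    blank_interference,
    carryover,
    cv_pct,
    dev_pct,
    dilution_integrity,
    pa_table,
    paired_matrix_comparison,
    stability_contrast,
)


def test_cv_pct():
    assert cv_pct([10, 10, 10]) == 0.0
    assert cv_pct([8, 10, 12]) == pytest.approx(20.0)  # sd 2, mean 10
    with pytest.raises(ValueError):
        cv_pct([5.0])


def test_dev_pct():
    assert dev_pct([2, 2, 2], 2) == 0.0
    assert dev_pct([9, 11], 10) == 0.0
    assert dev_pct([1.08, 1.12], 1) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        dev_pct([], 1.0)
    with pytest.raises(ValueError):
        dev_pct([1.0], 0.0)


def test_cv_and_dev_monte_carlo_consistency():
    rng = np.random.default_rng(11)
    values = 10.0 * (1 + rng.normal(0, 0.05, size=1000))
    assert cv_pct(values) == pytest.approx(5.0, abs=0.5)
    assert abs(dev_pct(values, 10.0)) < 1.0


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(0.1, 1000), st.lists(st.floats(0.5, 2.0), min_size=2, max_size=8))
def test_scale_invariance(scale, rel_values):
    nominal = 10.0
    values = [nominal * v for v in rel_values]
    scaled = [scale * v for v in values]
    assert cv_pct(scaled) == pytest.approx(cv_pct(values), rel=1e-9)
    assert dev_pct(scaled, scale * nominal) == pytest.approx(
        dev_pct(values, nominal), rel=1e-9, abs=1e-9)


def _qc_obs(measured_by_run, nominal, level="QC-L", analyte="X"):
    rows = []
    for run, values in measured_by_run.items():
        for v in values:
            rows.append({"analyte": analyte, "level_label": level,
                         "nominal_conc": nominal, "measured_conc": v,
                         "run_id": run})
    return pd.DataFrame(rows)


def test_pa_table_constant_values_pass():
    obs = _qc_obs({"R1": [6.0] * 5}, nominal=6.0)
    table, results = pa_table(obs)
    row = table.iloc[0]
    assert row["inter_cv"] == 0.0 and row["inter_dev"] == 0.0
    assert row["n"] == 5
    assert all(r.passed for r in results)


def test_pa_table_inter_day_pools_all_replicates():
    obs = _qc_obs({"R1": [5.5, 6.0, 6.5], "R2": [6.2, 6.4, 6.6]}, nominal=6.0)
    table, _ = pa_table(obs)
    row = table.iloc[0]
    pooled = np.array([5.5, 6.0, 6.5, 6.2, 6.4, 6.6])
    assert row["n"] == 6
    assert row["inter_dev"] == pytest.approx(dev_pct(pooled, 6.0), rel=1e-12)
    # conservation: pooled %dev equals replicate-weighted mean of run %devs
    run_devs = [dev_pct([5.5, 6.0, 6.5], 6.0), dev_pct([6.2, 6.4, 6.6], 6.0)]
    assert row["inter_dev"] == pytest.approx(np.mean(run_devs), rel=1e-12)
    assert row["intra_dev_min"] == pytest.approx(min(run_devs))
    assert row["intra_dev_max"] == pytest.approx(max(run_devs))


def test_pa_table_large_bias_at_lloq_fails():
    """A +25% bias at the LLOQ breaches even the relaxed 20% limit."""
    obs = _qc_obs({"R1": [2.5] * 6, "R2": [2.5] * 6}, nominal=2.0, level="LLOQ")
    _, results = pa_table(obs)
    dev_flags = [r for r in results if r.criterion == "inter-day %dev"]
    assert dev_flags[0].limit_pct == 20.0
    assert not dev_flags[0].passed


def test_pa_table_optional_run_level_gate():
    """One bad run fails only when the stricter per-run rule is enabled."""
    obs = _qc_obs({"R1": [6.0] * 5, "R2": [7.2] * 5}, nominal=6.0)
    _, default_flags = pa_table(obs)
    assert all(r.passed for r in default_flags)  # pooled dev is 10%
    _, strict_flags = pa_table(obs, flag_intra_runs=True)
    worst = [r for r in strict_flags if "worst run" in r.criterion
             and "%dev" in r.criterion]
    assert not worst[0].passed  # run R2 sits at +20%


def test_pa_table_parameter_recovery_large_n():
    """Inter-day %dev → bias and %CV → dispersion as n grows (3·SE)."""
    rng = np.random.default_rng(3)
    beta, gamma = 0.08, 0.07
    n = 1000
    values = 6.0 * (1 + beta) * (1 + rng.normal(0, gamma, size=n))
    obs = _qc_obs({"R1": values.tolist()}, nominal=6.0)
    table, _ = pa_table(obs)
    se_dev = 100 * gamma / math.sqrt(n)
    assert table.iloc[0]["inter_dev"] == pytest.approx(100 * beta, abs=3 * se_dev)
    se_cv = 100 * gamma / math.sqrt(2 * (n - 1))
    assert table.iloc[0]["inter_cv"] == pytest.approx(100 * gamma, abs=3 * se_cv)


def test_dilution_integrity():
    exact = dilution_integrity([400.0] * 5, 10, 4000)
    assert exact["dev_pct"] == 0.0 and exact["passed"]
    # mean 456 after 10x dilution of a 4000 ng/mL sample: +14%, passes
    high = dilution_integrity([456.0, 456.0, 456.0, 456.0, 456.0], 10, 4000)
    assert high["dev_pct"] == pytest.approx(14.0)
    assert high["passed"]
    low = dilution_integrity([330.0] * 5, 10, 4000)
    assert low["dev_pct"] == pytest.approx(-17.5)
    assert not low["passed"]
    with pytest.raises(ValueError):
        dilution_integrity([400.0] * 5, 0, 4000)
    with pytest.raises(ValueError):
        dilution_integrity([400.0, 410.0], 10, 4000)


def test_blank_interference_reference_values():
    hcq = blank_interference(839, 29900)
    assert round(hcq.observed_pct, 1) == 2.8 and hcq.passed
    bdcq = blank_interference(775, 8490)
    assert round(bdcq.observed_pct, 1) == 9.1 and bdcq.passed
    zero = blank_interference(0, 12345)
    assert zero.observed_pct == 0.0 and zero.passed
    with pytest.raises(ValueError):
        blank_interference(-1, 100)


def test_carryover_reference_values():
    dhcq = carryover(1050, 6240)
    assert round(dhcq.observed_pct, 1) == 16.8 and dhcq.passed
    hcq_is = carryover(1250, 83800, limit_pct=5)
    assert round(hcq_is.observed_pct, 1) == 1.5 and hcq_is.passed
    fail = carryover(1300, 6240)
    assert round(fail.observed_pct, 1) == 20.8 and not fail.passed


def test_stability_contrast():
    ok = stability_contrast([5.98, 5.98, 5.98], 6.0, mode="vs_nominal")
    assert ok.observed_pct == pytest.approx(99.7, abs=0.05)
    assert ok.passed
    same = stability_contrast([4.0, 4.1, 3.9], [4.0, 4.1, 3.9], mode="vs_control")
    assert same.observed_pct == pytest.approx(0.0, abs=1e-9) and same.passed
    degraded = stability_contrast([4.8, 4.8, 4.8], 6.0, mode="vs_nominal")
    assert degraded.observed_pct == pytest.approx(80.0)
    assert not degraded.passed
    with pytest.raises(ValueError):
        stability_contrast([1.0, 2.0], 1.5, mode="vs_nominal")
    with pytest.raises(ValueError):
        stability_contrast([1.0, 2.0, 3.0], [], mode="vs_control")


def test_paired_matrix_comparison():
    control = [1.0, 1.0, 1.0]
    results = paired_matrix_comparison(
        [[0.92, 0.92, 0.92], [0.80, 0.80, 0.80]], control)
    assert results[0].observed_pct == pytest.approx(-8.0)
    assert results[0].passed
    assert results[1].observed_pct == pytest.approx(-20.0)
    assert not results[1].passed
    identical = paired_matrix_comparison([control], control)
    assert identical[0].observed_pct == 0.0 and identical[0].passed


@pytest.mark.parametrize("limit,two_sided", [(15.0, True), (20.0, False)])
def test_acceptance_flag_flips_exactly_at_limit(limit, two_sided):
    """Acceptance is a pure threshold: crossing the limit flips the flag."""
    make = AcceptanceResult.two_sided if two_sided else AcceptanceResult.one_sided
    eps = 1e-9
    assert make("c", limit - eps, limit).passed
    assert make("c", limit, limit).passed  # boundary counts as passing
    assert not make("c", limit + eps, limit).passed
    if two_sided:
        assert make("c", -(limit - eps), limit).passed
        assert not make("c", -(limit + eps), limit).passed
    else:
        assert make("c", -999.0, limit).passed
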