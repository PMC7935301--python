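"""Bioanalytical method-validation statistics with acceptance flags.

Implements the standard validation battery for a quantitative LC-MS/MS
assay: intra-/inter-day precision and accuracy of quality-control (QC)
samples, dilution integrity, blank interference and carryover, stability
contrasts, and treated-versus-control matrix comparisons (hemolysis,
anticoagulant counter-ion).  Every statistic is paired with a pass/fail flag
against the regulatory limits: ±15% for precision and accuracy (±20% at the
LLOQ), blank and carryover signal ≤20% of the LLOQ response in the analyte
channel and ≤5% in the IS channel, stability within 100±15% remaining or
±15% difference from controls.

Operations consume measured *concentrations*; converting raw peak areas to
concentrations through a calibration fit is the caller's job (see
:mod:`mrmvalid.calibration`), which keeps the statistics layer independent
of the regression layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "AcceptanceResult",
    "cv_pct",
    "dev_pct",
    "pa_table",
    "dilution_integrity",
    "blank_interference",
    "carryover",
    "stability_contrast",
    "paired_matrix_comparison",
    "DEFAULT_LIMIT_PCT",
    "LLOQ_LIMIT_PCT",
    "BLANK_LIMIT_PCT",
    "IS_BLANK_LIMIT_PCT",
]

DEFAULT_LIMIT_PCT = 15.0
LLOQ_LIMIT_PCT = 20.0
BLANK_LIMIT_PCT = 20.0
IS_BLANK_LIMIT_PCT = 5.0


@dataclass(frozen=True)
class AcceptanceResult:
    """One validation criterion: observed value, limit, and verdict."""

    criterion: str
    observed_pct: float
    limit_pct: float
    passed: bool
    context: str = ""

    @staticmethod
    def two_sided(criterion: str, observed_pct: float, limit_pct: float,
                  context: str = "") -> "AcceptanceResult":
        return AcceptanceResult(criterion, observed_pct, limit_pct,
                                abs(observed_pct) <= limit_pct, context)

    @staticmethod
    def one_sided(criterion: str, observed_pct: float, limit_pct: float,
                  context: str = "") -> "AcceptanceResult":
        return AcceptanceResult(criterion, observed_pct, limit_pct,
                                observed_pct <= limit_pct, context)


def cv_pct(values: Sequence[float]) -> float:
    """Coefficient of variation: 100 × sample SD (n−1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("%CV needs at least 2 replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("%CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def dev_pct(values: Sequence[float], nominal: float) -> float:
    """Accuracy: 100 × (mean(values) − nominal) / nominal."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("%dev needs at least one value")
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return float(100.0 * (arr.mean() - nominal) / nominal)


def _qc_frame(observations: Union[pd.DataFrame, Sequence]) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations.copy()
    else:
        df = pd.DataFrame([vars(o) if not isinstance(o, dict) else o
                           for o in observations])
    required = {"analyte", "level_label", "nominal_conc", "measured_conc", "run_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"QC observations missing columns: {sorted(missing)}")
    if df["nominal_conc"].isna().any():
        bad = df.loc[df["nominal_conc"].isna(), "level_label"].unique()
        raise ValueError(f"missing nominal concentration for level(s) {list(bad)}")
    return df


def pa_table(
    observations: Union[pd.DataFrame, Sequence],
    limit_pct: float = DEFAULT_LIMIT_PCT,
    lloq_limit_pct: float = LLOQ_LIMIT_PCT,
    lloq_label: str = "LLOQ",
    flag_intra_runs: bool = False,
) -> Tuple[pd.DataFrame, List[AcceptanceResult]]:
    """Precision-and-accuracy summary per analyte × QC level.

    For each analyte/level cell the table reports the intra-day %CV and %dev
    range over runs, the inter-day %CV and %dev pooling every replicate of
    every run, and the pooled replicate count ``n``.  Acceptance flags
    compare the inter-day statistics against ``limit_pct``
    (``lloq_limit_pct`` for the LLOQ level); per-run intra-day values are
    always tabulated, and ``flag_intra_runs=True`` additionally gates the
    worst run's %CV and %dev — a stricter run-level rule some laboratories
    apply on top of the per-statistic thresholds.

    ``observations`` is a DataFrame (or sequence of records) with columns
    ``analyte, level_label, nominal_conc, measured_conc, run_id``.
    """
    df = _qc_frame(observations)
    rows = []
    results: List[AcceptanceResult] = []
    for (analyte, level), grp in df.groupby(["analyte", "level_label"], sort=False):
        nominals = grp["nominal_conc"].unique()
        if len(nominals) != 1:
            raise ValueError(
                f"level {level!r} of {analyte!r} has conflicting nominals {nominals}"
            )
        nominal = float(nominals[0])
        limit = lloq_limit_pct if level == lloq_label else limit_pct
        intra_cv, intra_dev = [], []
        for _, run in grp.groupby("run_id", sort=False):
            vals = run["measured_conc"].to_numpy()
            if len(vals) >= 2:
                intra_cv.append(cv_pct(vals))
            intra_dev.append(dev_pct(vals, nominal))
        pooled = grp["measured_conc"].to_numpy()
        inter_cv = cv_pct(pooled) if len(pooled) >= 2 else math.nan
        inter_dev = dev_pct(pooled, nominal)
        rows.append(
            {
                "analyte": analyte,
                "level_label": level,
                "nominal_conc": nominal,
                "n_runs": grp["run_id"].nunique(),
                "n": len(pooled),
                "intra_cv_min": min(intra_cv) if intra_cv else math.nan,
                "intra_cv_max": max(intra_cv) if intra_cv else math.nan,
                "intra_dev_min": min(intra_dev),
                "intra_dev_max": max(intra_dev),
                "inter_cv": inter_cv,
                "inter_dev": inter_dev,
                "limit_pct": limit,
            }
        )
        ctx = f"{analyte} {level}"
        results.append(AcceptanceResult.one_sided(
            "inter-day %CV", inter_cv, limit, ctx))
        results.append(AcceptanceResult.two_sided(
            "inter-day %dev", inter_dev, limit, ctx))
        if flag_intra_runs:
            worst_cv = max(intra_cv) if intra_cv else math.nan
            worst_dev = max(intra_dev, key=abs)
            results.append(AcceptanceResult.one_sided(
                "intra-day %CV (worst run)", worst_cv, limit, ctx))
            results.append(AcceptanceResult.two_sided(
                "intra-day %dev (worst run)", worst_dev, limit, ctx))
    return pd.DataFrame(rows), results


def dilution_integrity(
    measured_diluted: Sequence[float],
    dilution_factor: float,
    nominal_undiluted: float,
    limit_pct: float = DEFAULT_LIMIT_PCT,
) -> Dict[str, Union[float, AcceptanceResult]]:
    """Accuracy and precision of over-range samples after dilution.

    ``measured_diluted`` are back-calculated concentrations of the diluted
    replicates; the dilution-corrected mean is compared to the undiluted
    nominal.  Passes when both |%dev| and %CV are within ``limit_pct``.
    """
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    vals = np.asarray(measured_diluted, dtype=float)
    if vals.size < 3:
        raise ValueError("dilution integrity needs at least 3 replicates")
    corrected = vals * dilution_factor
    dev = dev_pct(corrected, nominal_undiluted)
    cv = cv_pct(vals)
    dev_res = AcceptanceResult.two_sided("dilution %dev", dev, limit_pct)
    cv_res = AcceptanceResult.one_sided("dilution %CV", cv, limit_pct)
    return {
        "dev_pct": dev,
        "cv_pct": cv,
        "dev_result": dev_res,
        "cv_result": cv_res,
        "passed": dev_res.passed and cv_res.passed,
    }


def blank_interference(
    blank_area: float,
    lloq_area: float,
    limit_pct: float = BLANK_LIMIT_PCT,
    context: str = "",
) -> AcceptanceResult:
    """Blank signal at the analyte's retention time as percent of LLOQ signal."""
    if blank_area < 0 or lloq_area <= 0:
        raise ValueError("areas must be non-negative with a positive LLOQ area")
    observed = 100.0 * blank_area / lloq_area
    return AcceptanceResult.one_sided("blank interference", observed, limit_pct, context)


def carryover(
    double_blank_area_after_uloq: float,
    lloq_area: float,
    limit_pct: float = BLANK_LIMIT_PCT,
    context: str = "",
) -> AcceptanceResult:
    """Residual signal in a double blank injected after the top calibrator.

    Same percent-of-LLOQ computation as blank interference; the conventional
    limits are 20% in the analyte channel and 5% of the IS response in the IS
    channel (pass ``limit_pct=5`` and the IS area of the LLOQ injection).
    """
    if double_blank_area_after_uloq < 0 or lloq_area <= 0:
        raise ValueError("areas must be non-negative with a positive LLOQ area")
    observed = 100.0 * double_blank_area_after_uloq / lloq_area
    return AcceptanceResult.one_sided("carryover", observed, limit_pct, context)


def stability_contrast(
    treated: Sequence[float],
    reference: Union[float, Sequence[float]],
    mode: str = "vs_nominal",
    limit_pct: float = DEFAULT_LIMIT_PCT,
    context: str = "",
) -> AcceptanceResult:
    """Stability of stressed samples versus nominal or fresh controls.

    ``mode="vs_nominal"`` reports percent remaining, ``100 × mean(treated) /
    nominal``, and passes within ``100 ± limit_pct``.  ``mode="vs_control"``
    reports the percent difference of means versus a fresh-control replicate
    set and passes within ``± limit_pct``.
    """
    vals = np.asarray(treated, dtype=float)
    if vals.size < 3:
        raise ValueError("stability needs at least 3 treated replicates")
    if mode == "vs_nominal":
        nominal = float(reference)  # type: ignore[arg-type]
        if nominal <= 0:
            raise ValueError("nominal must be positive")
        remaining = 100.0 * vals.mean() / nominal
        return AcceptanceResult(
            "stability % remaining", remaining, limit_pct,
            abs(remaining - 100.0) <= limit_pct, context,
        )
    if mode == "vs_control":
        control = np.asarray(reference, dtype=float)
        if control.size == 0:
            raise ValueError("empty control replicate set")
        if control.mean() == 0:
            raise ValueError("control mean is zero")
        diff = 100.0 * (vals.mean() - control.mean()) / control.mean()
        return AcceptanceResult.two_sided("stability % difference", diff,
                                          limit_pct, context)
    raise ValueError(f"unknown mode {mode!r}; expected 'vs_nominal' or 'vs_control'")


def paired_matrix_comparison(
    test_lots: Sequence[Sequence[float]],
    control_lot: Sequence[float],
    limit_pct: float = DEFAULT_LIMIT_PCT,
    lot_labels: Optional[Sequence[str]] = None,
) -> List[AcceptanceResult]:
    """Percent difference of each test matrix lot versus the control lot.

    Used for anticoagulant counter-ion and hemolysis studies: each test lot's
    replicate mean is compared to the control lot's mean and must fall within
    ``± limit_pct``.
    """
    control = np.asarray(control_lot, dtype=float)
    if control.size < 3:
        raise ValueError("control lot needs at least 3 replicates")
    if not test_lots:
        raise ValueError("no test lots supplied")
    if lot_labels is None:
        lot_labels = [f"lot {i + 1}" for i in range(len(test_lots))]
    results = []
    for label, lot in zip(lot_labels, test_lots):
        vals = np.asarray(lot, dtype=float)
        if vals.size < 3:
            raise ValueError(f"test {label} needs at least 3 replicates")
        diff = 100.0 * (vals.mean() - control.mean()) / control.mean()
        results.append(AcceptanceResult.two_sided(
            "matrix % difference", diff, limit_pct, label))
    return results
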