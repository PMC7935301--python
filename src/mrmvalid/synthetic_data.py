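"""Seeded synthetic peak-area datasets shaped like a validation campaign.

No raw instrument data ships with a typical published LC-MS/MS validation,
so this module generates peak-area records with the statistical structure
the validation battery assumes: nine-level calibration series replicated
over runs, multi-day QC replicates with configurable per-level bias and
between-run shifts, the three-set matrix-effect design, blank and
post-ULOQ double-blank injections expressed as fractions of the LLOQ
signal, stability arms with known degradation factors, and over-range
dilution samples.

The noise model is multiplicative Gaussian truncated at zero: a replicate's
effective concentration is ``nominal × (1 + bias) × (1 + run shift) ×
(1 + ε)`` with ``ε ~ N(0, response_cv)``, converted to an analyte area
through the analyte's true response curve and an independently drawn IS
area.  Proportional error of this kind is the standard justification for
1/x²-weighted calibration and yields near-constant %CV across levels, the
pattern real QC tables show.  Between-run variability is a single relative
shift per run — the simplest structure that separates intra- from
inter-day precision.

Every generator draws from ``numpy.random.default_rng`` seeded by the
config seed, a stage code, and the analyte index, so a fixed
:class:`SimConfig` reproduces byte-identical datasets regardless of which
stages are generated or in what order.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteSim",
    "SimConfig",
    "default_config",
    "simulate_calibration",
    "simulate_qc_runs",
    "simulate_me_experiment",
    "simulate_blanks_and_carryover",
    "simulate_stability_and_dilution",
    "simulate_all",
    "RECORD_COLUMNS",
    "ROLES",
]

RECORD_COLUMNS = [
    "sample_id", "role", "analyte", "level_label", "condition",
    "nominal_conc", "analyte_area", "is_area", "run_id",
]

ROLES = (
    "calibrator", "qc", "blank", "double_blank_after_uloq",
    "me_set1", "me_set2", "me_set3",
    "stability_treated", "stability_control", "dilution",
)

_STAGE = {"calibration": 1, "qc": 2, "me": 3, "blank": 4, "stability": 5}


@dataclass
class AnalyteSim:
    """Ground truth for one analyte's simulated assay."""

    name: str
    formula: str
    label_shift: int
    lloq: float
    uloq: float
    calibration_levels: Tuple[float, ...]
    curve_a: float = 0.0
    curve_b: float = 0.002
    curve_c: float = 0.0
    response_cv: float = 0.05
    run_shift_sd: float = 0.02
    is_area_mean: float = 8.0e4
    is_area_cv: float = 0.03
    qc_nominals: Dict[str, float] = field(default_factory=dict)
    qc_bias: Dict[str, float] = field(default_factory=dict)
    me_true_pct: Dict[str, float] = field(default_factory=dict)
    re_true_pct: Dict[str, float] = field(default_factory=dict)
    is_me_true_pct: Dict[str, float] = field(default_factory=dict)
    is_re_true_pct: Dict[str, float] = field(default_factory=dict)
    blank_fraction: float = 0.03
    carryover_fraction: float = 0.10
    is_blank_fraction: float = 0.0
    is_carryover_fraction: float = 0.015
    me_channel_residual_cv: float = 0.02
    degradation: Dict[str, float] = field(default_factory=dict)
    dilution_factor: float = 10.0
    dilution_nominal: Optional[float] = None  # defaults to 4 × ULOQ

    def true_ratio(self, conc: np.ndarray | float) -> np.ndarray | float:
        return self.curve_a + self.curve_b * np.asarray(conc, dtype=float) \
            + self.curve_c * np.asarray(conc, dtype=float) ** 2

    def validate(self) -> None:
        if self.lloq <= 0 or self.uloq <= self.lloq:
            raise ValueError(f"{self.name}: need 0 < LLOQ < ULOQ")
        if not self.calibration_levels:
            raise ValueError(f"{self.name}: no calibration levels")
        if min(self.calibration_levels) <= 0:
            raise ValueError(f"{self.name}: calibration levels must be positive")
        for label, cv in [("response_cv", self.response_cv),
                          ("run_shift_sd", self.run_shift_sd),
                          ("is_area_cv", self.is_area_cv)]:
            if cv < 0:
                raise ValueError(f"{self.name}: {label} must be >= 0")
        ratios = self.true_ratio(np.asarray(self.calibration_levels))
        if np.any(ratios <= 0):
            raise ValueError(
                f"{self.name}: true curve gives non-positive response inside range"
            )
        for level, nominal in self.qc_nominals.items():
            if nominal <= 0:
                raise ValueError(f"{self.name}: QC nominal for {level} must be > 0")


@dataclass
class SimConfig:
    """Full campaign design: analytes plus replication structure."""

    seed: int
    analytes: List[AnalyteSim]
    n_runs: int = 4
    n_reps: int = 6
    me_reps: int = 3
    stability_reps: int = 3
    dilution_reps: int = 5

    def validate(self) -> None:
        if not self.analytes:
            raise ValueError("config has no analytes")
        for a in self.analytes:
            a.validate()
        for label, n in [("n_runs", self.n_runs), ("n_reps", self.n_reps),
                         ("me_reps", self.me_reps),
                         ("stability_reps", self.stability_reps),
                         ("dilution_reps", self.dilution_reps)]:
            if n < 1:
                raise ValueError(f"{label} must be >= 1")

    def analyte(self, name: str) -> Tuple[int, AnalyteSim]:
        for i, a in enumerate(self.analytes):
            if a.name == name:
                return i, a
        raise KeyError(f"unknown analyte {name!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(seed: int = 0) -> SimConfig:
    """Four-analyte campaign mirroring a plasma HCQ/metabolites/AZM assay.

    Ranges 2–1000 (AZM, HCQ), 1–500 (DHCQ) and 0.5–250 ng/mL (BDCQ) over
    nine calibrators; QC levels at the LLOQ, 3×LLOQ (low), mid-range and 80%
    of ULOQ; 4 runs × 6 replicates; triplicate three-set matrix-effect
    design at the QC levels; blank and carryover signal fractions, QC
    biases, matrix-effect/recovery truths and degradation factors of
    realistic magnitude for a well-behaved assay.  AZM carries mild
    saturation curvature (negative quadratic term), the chloroquines are
    linear.
    """
    def series(lloq: float) -> Tuple[float, ...]:
        return tuple(lloq * f for f in (1, 2.5, 5, 10, 25, 50, 100, 250, 500))

    def qc(lloq: float) -> Dict[str, float]:
        return {"LLOQ": lloq, "QC-L": 3 * lloq, "QC-M": 30 * lloq,
                "QC-H": 400 * lloq}

    degradation = {"freeze_thaw": 0.97, "rt_66hr": 0.97, "long_term_38d": 0.96}
    analytes = [
        AnalyteSim(
            name="AZM", formula="C38H72N2O12", label_shift=5,
            lloq=2.0, uloq=1000.0, calibration_levels=series(2.0),
            curve_a=0.0, curve_b=0.003, curve_c=-3.0e-7,
            qc_nominals=qc(2.0),
            qc_bias={"LLOQ": -0.04, "QC-L": 0.04, "QC-M": 0.02, "QC-H": 0.04},
            me_true_pct={"low": 100.0, "med": 98.8, "high": 97.9},
            re_true_pct={"low": 102.0, "med": 99.4, "high": 98.6},
            is_me_true_pct={"low": 102.0, "med": 96.4, "high": 95.7},
            is_re_true_pct={"low": 101.0, "med": 100.0, "high": 102.0},
            blank_fraction=0.037, carryover_fraction=0.086,
            is_carryover_fraction=0.0, degradation=dict(degradation),
        ),
        AnalyteSim(
            name="HCQ", formula="C18H26ClN3O", label_shift=4,
            lloq=2.0, uloq=1000.0, calibration_levels=series(2.0),
            curve_a=0.0, curve_b=0.0025,
            qc_nominals=qc(2.0),
            qc_bias={"LLOQ": 0.04, "QC-L": 0.0, "QC-M": 0.0, "QC-H": -0.01},
            me_true_pct={"low": 110.0, "med": 98.0, "high": 103.0},
            re_true_pct={"low": 90.5, "med": 94.4, "high": 88.9},
            is_me_true_pct={"low": 106.0, "med": 101.0, "high": 100.0},
            is_re_true_pct={"low": 96.1, "med": 97.2, "high": 94.1},
            blank_fraction=0.028, carryover_fraction=0.10,
            is_carryover_fraction=0.015, degradation=dict(degradation),
        ),
        AnalyteSim(
            name="DHCQ", formula="C16H22ClN3O", label_shift=4,
            lloq=1.0, uloq=500.0, calibration_levels=series(1.0),
            curve_a=0.0, curve_b=0.004,
            qc_nominals=qc(1.0),
            qc_bias={"LLOQ": 0.01, "QC-L": -0.04, "QC-M": 0.0, "QC-H": -0.02},
            me_true_pct={"low": 102.0, "med": 101.0, "high": 106.0},
            re_true_pct={"low": 88.6, "med": 90.3, "high": 92.9},
            is_me_true_pct={"low": 103.0, "med": 98.9, "high": 104.0},
            is_re_true_pct={"low": 99.8, "med": 99.3, "high": 96.7},
            blank_fraction=0.058, carryover_fraction=0.168,
            is_carryover_fraction=0.0, degradation=dict(degradation),
        ),
        AnalyteSim(
            name="BDCQ", formula="C14H18ClN3", label_shift=4,
            lloq=0.5, uloq=250.0, calibration_levels=series(0.5),
            curve_a=0.0, curve_b=0.005,
            qc_nominals=qc(0.5),
            qc_bias={"LLOQ": 0.01, "QC-L": -0.03, "QC-M": -0.04, "QC-H": -0.04},
            me_true_pct={"low": 97.1, "med": 103.0, "high": 101.0},
            re_true_pct={"low": 90.9, "med": 88.7, "high": 89.0},
            is_me_true_pct={"low": 100.0, "med": 104.0, "high": 101.0},
            is_re_true_pct={"low": 91.8, "med": 94.0, "high": 87.7},
            blank_fraction=0.091, carryover_fraction=0.139,
            is_carryover_fraction=0.0, degradation=dict(degradation),
        ),
    ]
    return SimConfig(seed=seed, analytes=analytes)


def _rng(config: SimConfig, stage: str, analyte_idx: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STAGE[stage], analyte_idx])


def _areas(
    analyte: AnalyteSim,
    conc: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (analyte_area, is_area) for effective concentrations ``conc``."""
    ratio = np.maximum(analyte.true_ratio(conc), 0.0)
    is_area = analyte.is_area_mean * (1.0 + rng.normal(0.0, analyte.is_area_cv,
                                                       size=len(conc)))
    is_area = np.maximum(is_area, 1.0)  # IS area must stay positive
    return np.maximum(ratio * is_area, 0.0), is_area


def _frame(rows: List[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def simulate_calibration(config: SimConfig, analyte_name: str) -> pd.DataFrame:
    """One nine-level calibration series per run for ``analyte_name``."""
    config.validate()
    idx, analyte = config.analyte(analyte_name)
    rng = _rng(config, "calibration", idx)
    rows: List[dict] = []
    for run in range(1, config.n_runs + 1):
        levels = np.asarray(analyte.calibration_levels, dtype=float)
        eff = levels * np.maximum(
            1.0 + rng.normal(0.0, analyte.response_cv, size=len(levels)), 0.0
        )
        area, is_area = _areas(analyte, eff, rng)
        for i, (lev, a_area, i_area) in enumerate(zip(levels, area, is_area), 1):
            rows.append({
                "sample_id": f"{analyte_name}-cal-R{run}-L{i}",
                "role": "calibrator", "analyte": analyte_name,
                "level_label": f"CAL-{i}", "condition": "",
                "nominal_conc": lev, "analyte_area": a_area,
                "is_area": i_area, "run_id": f"R{run}",
            })
    return _frame(rows)


def simulate_qc_runs(config: SimConfig, analyte_name: str) -> pd.DataFrame:
    """Replicated QC injections across runs with per-level bias and run shifts."""
    config.validate()
    idx, analyte = config.analyte(analyte_name)
    rng = _rng(config, "qc", idx)
    rows: List[dict] = []
    for run in range(1, config.n_runs + 1):
        run_shift = rng.normal(0.0, analyte.run_shift_sd)
        for level, nominal in analyte.qc_nominals.items():
            bias = analyte.qc_bias.get(level, 0.0)
            eps = rng.normal(0.0, analyte.response_cv, size=config.n_reps)
            eff = nominal * (1.0 + bias) * (1.0 + run_shift) * np.maximum(1.0 + eps, 0.0)
            area, is_area = _areas(analyte, eff, rng)
            for rep in range(config.n_reps):
                rows.append({
                    "sample_id": f"{analyte_name}-qc-R{run}-{level}-{rep + 1}",
                    "role": "qc", "analyte": analyte_name,
                    "level_label": level, "condition": "",
                    "nominal_conc": nominal, "analyte_area": area[rep],
                    "is_area": is_area[rep], "run_id": f"R{run}",
                })
    return _frame(rows)


def simulate_me_experiment(config: SimConfig, analyte_name: str) -> pd.DataFrame:
    """Three-set matrix-effect design at low/med/high QC concentrations."""
    config.validate()
    idx, analyte = config.analyte(analyte_name)
    rng = _rng(config, "me", idx)
    level_map = {"low": "QC-L", "med": "QC-M", "high": "QC-H"}
    rows: List[dict] = []
    for level, qc_level in level_map.items():
        nominal = analyte.qc_nominals[qc_level]
        base_ratio = float(analyte.true_ratio(nominal))
        me = analyte.me_true_pct.get(level, 100.0) / 100.0
        re = analyte.re_true_pct.get(level, 100.0) / 100.0
        me_is = analyte.is_me_true_pct.get(level, 100.0) / 100.0
        re_is = analyte.is_re_true_pct.get(level, 100.0) / 100.0
        set_factor = {
            "me_set1": (1.0, 1.0),
            "me_set2": (me, me_is),
            "me_set3": (me * re, me_is * re_is),
        }
        for set_id, (f_analyte, f_is) in set_factor.items():
            for rep in range(config.me_reps):
                # Both channels of one injection share the ionization /
                # volume factor; only small residuals are channel-specific.
                shared = max(1.0 + rng.normal(0.0, analyte.response_cv), 0.0)
                res = analyte.me_channel_residual_cv
                noise_a = shared * max(1.0 + rng.normal(0.0, res), 0.0)
                noise_i = shared * max(1.0 + rng.normal(0.0, res), 0.0)
                is_area = analyte.is_area_mean * f_is * noise_i
                a_area = base_ratio * analyte.is_area_mean * f_analyte * noise_a
                rows.append({
                    "sample_id": f"{analyte_name}-{set_id}-{level}-{rep + 1}",
                    "role": set_id, "analyte": analyte_name,
                    "level_label": level, "condition": "",
                    "nominal_conc": nominal, "analyte_area": max(a_area, 0.0),
                    "is_area": max(is_area, 1.0), "run_id": "ME",
                })
    return _frame(rows)


def simulate_blanks_and_carryover(config: SimConfig, analyte_name: str,
                                  n_blanks: int = 3) -> pd.DataFrame:
    """Blank and post-ULOQ double-blank injections as LLOQ-signal fractions."""
    config.validate()
    idx, analyte = config.analyte(analyte_name)
    rng = _rng(config, "blank", idx)
    lloq_area = float(analyte.true_ratio(analyte.lloq)) * analyte.is_area_mean
    rows: List[dict] = []
    for i in range(n_blanks):
        noise = max(1.0 + rng.normal(0.0, analyte.response_cv), 0.0)
        is_noise = max(1.0 + rng.normal(0.0, analyte.is_area_cv), 0.0)
        rows.append({
            "sample_id": f"{analyte_name}-blank-{i + 1}",
            "role": "blank", "analyte": analyte_name,
            "level_label": "", "condition": "",
            "nominal_conc": np.nan,
            "analyte_area": analyte.blank_fraction * lloq_area * noise,
            # blanks are processed with IS, so the IS channel carries signal
            "is_area": analyte.is_area_mean * is_noise,
            "run_id": "R1",
        })
    for i in range(n_blanks):
        noise = max(1.0 + rng.normal(0.0, analyte.response_cv), 0.0)
        rows.append({
            "sample_id": f"{analyte_name}-dblank-{i + 1}",
            "role": "double_blank_after_uloq", "analyte": analyte_name,
            "level_label": "", "condition": "",
            "nominal_conc": np.nan,
            "analyte_area": analyte.carryover_fraction * lloq_area * noise,
            # double blanks carry no IS; any IS-channel signal is carryover
            "is_area": analyte.is_carryover_fraction * analyte.is_area_mean,
            "run_id": "R1",
        })
    return _frame(rows)


def simulate_stability_and_dilution(config: SimConfig, analyte_name: str) -> pd.DataFrame:
    """Stability arms (treated + fresh controls) and 10-fold dilution samples."""
    config.validate()
    idx, analyte = config.analyte(analyte_name)
    rng = _rng(config, "stability", idx)
    rows: List[dict] = []
    for condition, remaining in analyte.degradation.items():
        for level in ("QC-L", "QC-H"):
            nominal = analyte.qc_nominals[level]
            for role, factor in (("stability_treated", remaining),
                                 ("stability_control", 1.0)):
                eps = rng.normal(0.0, analyte.response_cv, size=config.stability_reps)
                eff = nominal * factor * np.maximum(1.0 + eps, 0.0)
                area, is_area = _areas(analyte, eff, rng)
                for rep in range(config.stability_reps):
                    rows.append({
                        "sample_id": f"{analyte_name}-{condition}-{level}-"
                                     f"{role.split('_')[1]}-{rep + 1}",
                        "role": role, "analyte": analyte_name,
                        "level_label": level, "condition": condition,
                        "nominal_conc": nominal, "analyte_area": area[rep],
                        "is_area": is_area[rep], "run_id": "STAB",
                    })
    dilution_nominal = analyte.dilution_nominal or 4.0 * analyte.uloq
    diluted_conc = dilution_nominal / analyte.dilution_factor
    eps = rng.normal(0.0, analyte.response_cv, size=config.dilution_reps)
    eff = diluted_conc * np.maximum(1.0 + eps, 0.0)
    area, is_area = _areas(analyte, eff, rng)
    for rep in range(config.dilution_reps):
        rows.append({
            "sample_id": f"{analyte_name}-dilution-{rep + 1}",
            "role": "dilution", "analyte": analyte_name,
            "level_label": "DIL", "condition": f"DF{analyte.dilution_factor:g}",
            "nominal_conc": dilution_nominal, "analyte_area": area[rep],
            "is_area": is_area[rep], "run_id": "R1",
        })
    return _frame(rows)


def simulate_all(config: SimConfig) -> pd.DataFrame:
    """Every stage for every analyte, concatenated into one record table."""
    config.validate()
    frames = []
    for analyte in config.analytes:
        frames.append(simulate_calibration(config, analyte.name))
        frames.append(simulate_qc_runs(config, analyte.name))
        frames.append(simulate_me_experiment(config, analyte.name))
        frames.append(simulate_blanks_and_carryover(config, analyte.name))
        frames.append(simulate_stability_and_dilution(config, analyte.name))
    return pd.concat(frames, ignore_index=True)
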