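"""Matrix effect, recovery, and process efficiency (three-set design).

The classic post-extraction-spike experiment prepares, at each QC level:

* **Set 1** — analyte and IS in clean solution (no matrix, no extraction);
* **Set 2** — spiked into blank-matrix *extract* (matrix, no extraction loss);
* **Set 3** — spiked into blank matrix *before* extraction (matrix + loss).

From the mean peak areas of each set,

    ME = 100 × set2 / set1      (ionization suppression/enhancement)
    RE = 100 × set3 / set2      (extraction recovery)
    PE = 100 × set3 / set1      (overall process efficiency)

and PE = ME × RE / 100 holds identically.  Both the analyte and the IS
areas are summarized; the IS-normalized matrix effect, 100 × ME_analyte /
ME_IS, shows whether the co-eluting labelled IS tracks the analyte's
suppression (an alternative normalization — ME computed on the analyte/IS
response ratio — is available via ``is_normalization="ratio"`` and is
numerically identical when the same replicates pair up).
"""

from __future__ import annotations

from typing import List, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "matrix_effect",
    "recovery",
    "process_efficiency",
    "summarize_me_experiment",
    "SET_LABELS",
]

SET_LABELS = ("me_set1", "me_set2", "me_set3")


def _ratio_pct(numerator: float, denominator: float, what: str) -> float:
    if denominator <= 0:
        raise ValueError(f"{what}: denominator mean area must be positive")
    if numerator < 0:
        raise ValueError(f"{what}: numerator mean area must be non-negative")
    return 100.0 * numerator / denominator


def matrix_effect(set2_mean_area: float, set1_mean_area: float) -> float:
    """ME% = 100 × post-extraction-spike area / clean-solution area."""
    return _ratio_pct(set2_mean_area, set1_mean_area, "matrix effect")


def recovery(set3_mean_area: float, set2_mean_area: float) -> float:
    """RE% = 100 × pre-extraction-spike area / post-extraction-spike area."""
    return _ratio_pct(set3_mean_area, set2_mean_area, "recovery")


def process_efficiency(set3_mean_area: float, set1_mean_area: float) -> float:
    """PE% = 100 × pre-extraction-spike area / clean-solution area."""
    return _ratio_pct(set3_mean_area, set1_mean_area, "process efficiency")


def summarize_me_experiment(
    records: Union[pd.DataFrame, Sequence],
    is_normalization: str = "me_ratio",
) -> pd.DataFrame:
    """ME/RE/PE summary per analyte × level from replicate peak areas.

    ``records`` must carry columns ``set_id`` (one of ``me_set1``,
    ``me_set2``, ``me_set3``), ``level``, ``analyte``, ``analyte_area``,
    ``is_area``, with at least 3 replicates per cell.  Returns one row per
    analyte × level with ME/RE/PE for the analyte and the IS, the
    IS-normalized ME, and the replicate %CV of the analyte areas per set.

    ``is_normalization="me_ratio"`` (default) computes 100 × ME_analyte /
    ME_IS from the two ME percentages; ``"ratio"`` computes ME on the mean
    analyte/IS response ratios directly.
    """
    if is_normalization not in ("me_ratio", "ratio"):
        raise ValueError("is_normalization must be 'me_ratio' or 'ratio'")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records])
    required = {"set_id", "level", "analyte", "analyte_area", "is_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ME records missing columns: {sorted(missing)}")
    unknown = set(df["set_id"].unique()) - set(SET_LABELS)
    if unknown:
        raise ValueError(f"unknown set_id values: {sorted(unknown)}")

    rows: List[dict] = []
    for (analyte, level), grp in df.groupby(["analyte", "level"], sort=False):
        cells = {}
        for set_id in SET_LABELS:
            cell = grp[grp["set_id"] == set_id]
            if cell.empty:
                raise ValueError(f"missing {set_id} for analyte {analyte!r} level {level!r}")
            if len(cell) < 3:
                raise ValueError(
                    f"{set_id} for analyte {analyte!r} level {level!r} has "
                    f"{len(cell)} replicates; need >= 3"
                )
            cells[set_id] = cell
        mean_a = {s: cells[s]["analyte_area"].mean() for s in SET_LABELS}
        mean_i = {s: cells[s]["is_area"].mean() for s in SET_LABELS}
        mean_r = {
            s: (cells[s]["analyte_area"] / cells[s]["is_area"]).mean()
            for s in SET_LABELS
        }
        me_a = matrix_effect(mean_a["me_set2"], mean_a["me_set1"])
        re_a = recovery(mean_a["me_set3"], mean_a["me_set2"])
        pe_a = process_efficiency(mean_a["me_set3"], mean_a["me_set1"])
        me_i = matrix_effect(mean_i["me_set2"], mean_i["me_set1"])
        re_i = recovery(mean_i["me_set3"], mean_i["me_set2"])
        pe_i = process_efficiency(mean_i["me_set3"], mean_i["me_set1"])
        if is_normalization == "me_ratio":
            is_norm_me = 100.0 * me_a / me_i
        else:
            is_norm_me = matrix_effect(mean_r["me_set2"], mean_r["me_set1"])
        row = {
            "analyte": analyte,
            "level": level,
            "me_pct": me_a,
            "re_pct": re_a,
            "pe_pct": pe_a,
            "me_is_pct": me_i,
            "re_is_pct": re_i,
            "pe_is_pct": pe_i,
            "is_normalized_me_pct": is_norm_me,
        }
        for set_id in SET_LABELS:
            areas = cells[set_id]["analyte_area"].to_numpy(dtype=float)
            row[f"cv_{set_id}_pct"] = float(100.0 * areas.std(ddof=1) / areas.mean())
        rows.append(row)
    return pd.DataFrame(rows)
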