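"""Internal-standard concentration windows and MRM channel choice.

A deuterated internal standard (IS) sits a few nominal mass units above its
analyte, inside the analyte's natural isotopologue envelope.  Two cross-talk
constraints bound the usable IS concentration:

* the analyte's natural satellite at the IS channel must stay small relative
  to the IS signal — at the upper limit of quantitation (ULOQ) it should not
  exceed ``max_analyte_to_is_pct`` (default 5%) of the IS signal, giving a
  *minimum* IS concentration

      C_IS,min = m% * ULOQ / max_analyte_to_is_pct

  where ``m`` is the analyte's isotopologue abundance (percent of base) at
  the IS channel's nominal offset;

* any residual signal the IS leaks into the analyte channel must stay below
  ``max_is_to_analyte_pct`` (default 20%) of the signal at the lower limit of
  quantitation (LLOQ), giving a *maximum*

      C_IS,max = max_is_to_analyte_pct * LLOQ / n%

  with ``n`` the IS-to-analyte cross-signal percentage.  For fully deuterated
  labels ``n`` is typically negligible and defaults to 0, which leaves the
  window unbounded above.

For chlorinated analytes the ³⁷Cl satellite of the labelled IS (label shift
d plus 2) offers a channel where the analyte's natural abundance is orders of
magnitude lower than at d itself, shrinking C_IS,min dramatically; the
planner enumerates candidate channels and ranks them by C_IS,min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

from .isotopes import Formula, FormulaError, formula_to_string, isotope_pattern

__all__ = [
    "TransitionPlan",
    "min_is_concentration",
    "max_is_concentration",
    "labelled_formula",
    "plan_channels",
]

#: Default cross-talk tolerances, in percent.
DEFAULT_MAX_ANALYTE_TO_IS_PCT = 5.0
DEFAULT_MAX_IS_TO_ANALYTE_PCT = 20.0


@dataclass
class TransitionPlan:
    """One candidate IS channel with its feasible concentration window."""

    analyte_name: str
    is_name: str
    channel_offset_k: int
    m_pct: float
    n_pct: float
    uloq: float
    lloq: float
    c_is_min: float
    c_is_max: float
    is_channel_rel_signal_pct: float
    low_is_signal: bool
    chosen_c_is: Optional[float] = None

    @property
    def window_nonempty(self) -> bool:
        return self.c_is_min <= self.c_is_max


def min_is_concentration(
    m_pct: float,
    uloq: float,
    max_analyte_to_is_pct: float = DEFAULT_MAX_ANALYTE_TO_IS_PCT,
) -> float:
    """Lowest admissible IS concentration (same units as ``uloq``).

    ``m_pct`` is the analyte's cross-signal into the IS channel as a percent
    of its base peak.  Linear in both arguments.
    """
    if m_pct < 0:
        raise ValueError(f"cross-signal percentage must be non-negative, got {m_pct}")
    if uloq <= 0:
        raise ValueError(f"ULOQ must be positive, got {uloq}")
    if max_analyte_to_is_pct <= 0:
        raise ValueError("cross-talk tolerance must be positive")
    return m_pct * uloq / max_analyte_to_is_pct


def max_is_concentration(
    n_pct: float,
    lloq: float,
    max_is_to_analyte_pct: float = DEFAULT_MAX_IS_TO_ANALYTE_PCT,
) -> float:
    """Highest admissible IS concentration; ``inf`` when ``n_pct`` is 0.

    ``n_pct`` is the IS cross-signal into the analyte channel as a percent of
    the IS base peak.  A zero ``n_pct`` imposes no upper constraint and the
    unbounded window is reported as ``math.inf``.
    """
    if n_pct < 0:
        raise ValueError(f"cross-signal percentage must be non-negative, got {n_pct}")
    if lloq <= 0:
        raise ValueError(f"LLOQ must be positive, got {lloq}")
    if n_pct == 0:
        return math.inf
    return max_is_to_analyte_pct * lloq / n_pct


def labelled_formula(analyte_formula: Mapping[str, int], label_shift: int) -> Formula:
    """Formula of the deuterium-labelled analogue (``label_shift`` H -> D)."""
    if label_shift < 0:
        raise ValueError("label shift must be non-negative")
    formula = dict(analyte_formula)
    n_h = formula.get("H", 0)
    if n_h < label_shift:
        raise FormulaError(
            f"cannot place {label_shift} deuterium labels on a formula with {n_h} H"
        )
    if label_shift:
        formula["H"] = n_h - label_shift
        if formula["H"] == 0:
            del formula["H"]
        formula["D"] = formula.get("D", 0) + label_shift
    return formula


def plan_channels(
    analyte_formula: Mapping[str, int],
    label_shift: int,
    candidate_offsets: Sequence[int],
    lloq: float,
    uloq: float,
    is_signal_floor: float = 1.0,
    n_pct: float = 0.0,
    analyte_name: str = "",
    is_name: str = "",
    max_analyte_to_is_pct: float = DEFAULT_MAX_ANALYTE_TO_IS_PCT,
    max_is_to_analyte_pct: float = DEFAULT_MAX_IS_TO_ANALYTE_PCT,
) -> List[TransitionPlan]:
    """Rank candidate IS channels by the minimum IS concentration they allow.

    Each candidate offset ``k`` is a nominal-mass shift of the monitored IS
    precursor above the analyte's monoisotopic peak (typically the label
    shift ``d`` itself and, for chlorinated analytes, ``d + 2`` for the ³⁷Cl
    satellite).  The analyte's natural abundance at ``k`` fixes ``m`` and
    hence C_IS,min; the IS's own pattern abundance at ``k - label_shift``
    says how much signal the channel retains relative to the IS base peak —
    channels below ``is_signal_floor`` percent are flagged ``low_is_signal``
    but kept, since sensitivity trade-offs are the analyst's call.
    """
    if not candidate_offsets:
        raise ValueError("no candidate channel offsets supplied")
    analyte_pattern = isotope_pattern(analyte_formula, max_offset=max(candidate_offsets))
    is_form = labelled_formula(analyte_formula, label_shift)
    is_pattern = isotope_pattern(
        is_form, max_offset=max(max(candidate_offsets) - label_shift, 0)
    )
    if not analyte_name:
        analyte_name = formula_to_string(analyte_formula)
    if not is_name:
        is_name = formula_to_string(is_form)
    plans = []
    for k in candidate_offsets:
        if k < label_shift:
            raise ValueError(
                f"candidate offset {k} is below the label shift {label_shift}"
            )
        m_pct = analyte_pattern.abundance_at(k)
        rel_signal = is_pattern.abundance_at(k - label_shift)
        plans.append(
            TransitionPlan(
                analyte_name=analyte_name,
                is_name=is_name,
                channel_offset_k=int(k),
                m_pct=m_pct,
                n_pct=n_pct,
                uloq=uloq,
                lloq=lloq,
                c_is_min=min_is_concentration(m_pct, uloq, max_analyte_to_is_pct),
                c_is_max=max_is_concentration(n_pct, lloq, max_is_to_analyte_pct),
                is_channel_rel_signal_pct=rel_signal,
                low_is_signal=rel_signal < is_signal_floor,
            )
        )
    plans.sort(key=lambda plan: plan.c_is_min)
    return plans
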