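"""Isotope-pattern arithmetic for small-molecule MRM assay design.

Quantitative LC-MS/MS assays that use stable-isotope-labelled internal
standards must know how much natural isotopologue signal an analyte leaks
into the internal standard's mass channel (and vice versa).  This module
computes, from a plain molecular formula, the monoisotopic mass and the
relative abundance of each nominal-mass isotopologue bin (M, M+1, M+2, ...)
under natural isotope abundances.

The distribution is computed exactly: for each element the multinomial
expansion over its stable isotopes is evaluated with log-factorials, and the
per-element distributions are convolved.  Isotopologues are binned by their
integer nominal-mass offset from the all-lightest-isotope species, which is
how unit-resolution triple-quadrupole instruments see them; fine structure
within a bin is aggregated, and each bin carries the abundance-weighted
centroid mass of its members.

Deuterium is treated as a distinct pseudo-element ``D`` (mass 2.014102,
abundance 100%) so that labelled internal standards such as ``C18H22D4ClN3O``
can be handled with the same machinery: the label shifts the whole pattern
without broadening it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

import numpy as np

__all__ = [
    "ISOTOPES",
    "Formula",
    "IsotopeEntry",
    "IsotopePattern",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "nominal_distribution",
    "isotope_pattern",
    "abundance_at_offset",
]

#: Element -> list of (nominal mass offset from lightest isotope, exact mass
#: in Da, fractional natural abundance).  Values pinned from the CIAAW/NIST
#: standard atomic-weight compilation (2021 representative abundances) so the
#: package reproduces the same numbers on every machine.
ISOTOPES: Dict[str, List[Tuple[int, float, float]]] = {
    "H": [(0, 1.00782503207, 0.999885), (1, 2.01410177812, 0.000115)],
    "C": [(0, 12.0, 0.9893), (1, 13.00335483507, 0.0107)],
    "N": [(0, 14.00307400443, 0.99636), (1, 15.00010889888, 0.00364)],
    "O": [
        (0, 15.99491461957, 0.99757),
        (1, 16.99913175650, 0.00038),
        (2, 17.99915961286, 0.00205),
    ],
    "Cl": [(0, 34.968852682, 0.7576), (2, 36.965902602, 0.2424)],
    "S": [
        (0, 31.97207117, 0.9499),
        (1, 32.97145891, 0.0075),
        (2, 33.96786700, 0.0425),
        (4, 35.96708071, 0.0001),
    ],
    "P": [(0, 30.97376199842, 1.0)],
    "F": [(0, 18.99840316273, 1.0)],
    # Deuterium as a pure pseudo-element: a site known to carry the label.
    "D": [(0, 2.014102, 1.0)],
}

Formula = Dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


def parse_formula(text: str) -> Formula:
    """Parse an element-count string like ``"C18H26ClN3O"`` into a dict.

    Counts default to 1 when omitted; repeated symbols accumulate
    (``"CH3CH3"`` -> ``{"C": 2, "H": 6}``).

    Raises
    ------
    FormulaError
        If the string is empty, contains characters that are not element
        tokens, or names an element with no isotope data.
    """
    if not text or not text.strip():
        raise FormulaError("empty molecular formula")
    text = text.strip()
    formula: Formula = {}
    pos = 0
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(
                f"cannot parse formula {text!r} at position {pos} ({text[pos:]!r})"
            )
        symbol, count_str = match.groups()
        if symbol not in ISOTOPES:
            raise FormulaError(f"unsupported element symbol {symbol!r} in {text!r}")
        count = int(count_str) if count_str else 1
        formula[symbol] = formula.get(symbol, 0) + count
        pos = match.end()
    formula = {el: n for el, n in formula.items() if n > 0}
    if not formula:
        raise FormulaError(f"formula {text!r} contains no atoms")
    return formula


def formula_to_string(formula: Mapping[str, int]) -> str:
    """Hill-ish rendering (C, H first, then alphabetical) of a formula dict."""
    order = sorted(formula, key=lambda el: (el != "C", el != "H", el))
    return "".join(f"{el}{formula[el] if formula[el] != 1 else ''}" for el in order)


def _validate(formula: Mapping[str, int]) -> None:
    if not formula:
        raise FormulaError("empty molecular formula")
    for el, n in formula.items():
        if el not in ISOTOPES:
            raise FormulaError(f"unsupported element symbol {el!r}")
        if not isinstance(n, (int, np.integer)) or n < 0:
            raise FormulaError(f"element count for {el} must be a non-negative int, got {n!r}")
    if sum(formula.values()) < 1:
        raise FormulaError("formula contains no atoms")


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Mass in Da of the isotopologue built from each element's lightest isotope."""
    _validate(formula)
    return sum(n * ISOTOPES[el][0][1] for el, n in formula.items())


def _compositions(n: int, parts: int) -> Iterator[Tuple[int, ...]]:
    """All tuples of `parts` non-negative ints summing to n."""
    if parts == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, parts - 1):
            yield (first,) + rest


def _element_distribution(el: str, n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Multinomial offset distribution for ``n`` atoms of one element.

    Returns ``(p, s)`` indexed by nominal offset, where ``p[k]`` is the
    probability of total offset ``k`` and ``s[k]`` the probability-weighted
    total mass (so ``s[k]/p[k]`` is the centroid mass of the bin).
    Terms use log-factorials, so large atom counts stay stable.
    """
    isotopes = ISOTOPES[el]
    max_k = n * max(k for k, _, _ in isotopes)
    p = np.zeros(max_k + 1)
    s = np.zeros(max_k + 1)
    log_n_fact = math.lgamma(n + 1)
    for counts in _compositions(n, len(isotopes)):
        log_p = log_n_fact
        offset = 0
        mass = 0.0
        skip = False
        for c, (k, m, a) in zip(counts, isotopes):
            if c and a == 0.0:
                skip = True
                break
            log_p -= math.lgamma(c + 1)
            if c:
                log_p += c * math.log(a)
            offset += c * k
            mass += c * m
        if skip:
            continue
        prob = math.exp(log_p)
        p[offset] += prob
        s[offset] += prob * mass
    return p, s


def nominal_distribution(formula: Mapping[str, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Full un-normalized isotopologue distribution binned by nominal offset.

    Returns ``(probabilities, centroid_masses)`` as equal-length arrays over
    offsets ``0..K`` with no truncation: ``probabilities.sum() == 1`` up to
    float round-off.  ``centroid_masses[k]`` is NaN where the bin probability
    is zero.
    """
    _validate(formula)
    p = np.array([1.0])
    s = np.array([0.0])
    for el, n in formula.items():
        if n == 0:
            continue
        ep, es = _element_distribution(el, n)
        # convolve probabilities; the mass moment distributes over the product
        s = np.convolve(s, ep) + np.convolve(p, es)
        p = np.convolve(p, ep)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = np.where(p > 0, s / np.where(p > 0, p, 1.0), np.nan)
    return p, centroid


@dataclass(frozen=True)
class IsotopeEntry:
    offset: int
    mass_da: float
    rel_abundance_pct: float


@dataclass(frozen=True)
class IsotopePattern:
    """Relative isotopologue abundances of a formula, base peak = 100%."""

    formula: Formula
    entries: List[IsotopeEntry]
    base_offset: int
    prune_threshold: float = 0.0
    _by_offset: Dict[int, IsotopeEntry] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_offset", {e.offset: e for e in self.entries})

    def abundance_at(self, k: int) -> float:
        if k < 0:
            raise ValueError(f"nominal offset must be non-negative, got {k}")
        entry = self._by_offset.get(k)
        return entry.rel_abundance_pct if entry is not None else 0.0

    def mass_at(self, k: int) -> float:
        entry = self._by_offset.get(k)
        return entry.mass_da if entry is not None else math.nan


def isotope_pattern(
    formula: Mapping[str, int],
    prune_threshold: float = 1e-6,
    max_offset: int = 10,
) -> IsotopePattern:
    """Nominal-mass isotope pattern of ``formula``, normalized to the base bin.

    Parameters
    ----------
    formula:
        Element -> count mapping (see :func:`parse_formula`).
    prune_threshold:
        Bins beyond ``max_offset`` whose abundance falls below this fraction
        of the base peak are dropped.  Bins at or below ``max_offset`` are
        always kept, so tabulated satellites (M+4 ... M+6) survive pruning.
    max_offset:
        Guaranteed-reported span of offsets.

    The base peak (100%) is the most abundant bin.  For formulas dominated by
    light elements this is the monoisotopic bin; if it is not (e.g. many
    chlorines), an error is raised rather than silently renormalizing, since
    downstream cross-talk planning assumes base == monoisotopic.
    """
    p, centroid = nominal_distribution(formula)
    base = int(np.argmax(p))
    if base != 0:
        raise ValueError(
            "most abundant isotopologue bin is not the monoisotopic bin "
            f"(base offset {base}); pattern normalization convention violated"
        )
    # divide first so the base bin is exactly 100.0 in floating point
    rel = 100.0 * (p / p[base])
    entries = []
    for k in range(len(p)):
        if p[k] <= 0:
            continue
        if k > max_offset and rel[k] < 100.0 * prune_threshold:
            continue
        entries.append(IsotopeEntry(offset=k, mass_da=float(centroid[k]),
                                    rel_abundance_pct=float(rel[k])))
    return IsotopePattern(
        formula=dict(formula),
        entries=entries,
        base_offset=base,
        prune_threshold=prune_threshold,
    )


def abundance_at_offset(pattern: IsotopePattern, k: int) -> float:
    """Relative abundance (percent of base) of bin ``k``; 0 if absent."""
    return pattern.abundance_at(k)
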