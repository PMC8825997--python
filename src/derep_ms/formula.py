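"""Elemental-composition arithmetic and molecular-formula enumeration.

A high-resolution mass spectrometer measures the monoisotopic mass of an
analyte to low-ppm accuracy, which constrains — but does not uniquely
determine — its elemental composition.  This module provides the formula
primitives the dereplication workflow relies on: Hill-notation parsing,
monoisotopic mass summation, ring-plus-double-bond equivalents (RDBE),
the nitrogen rule, and exhaustive enumeration of candidate formulas for a
neutral mass within a ppm tolerance over a bounded CHNOPS element box.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_MASS",
    "MolecularFormula",
    "FormulaCandidate",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "rdbe",
    "nitrogen_rule_ok",
    "enumerate_formulas",
    "DEFAULT_ELEMENT_RANGES",
]

#: IUPAC monoisotopic atomic masses (Da) of the elements supported by default.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Element-count box searched by default: generous enough for typical
#: microbial secondary metabolites up to ~1200 Da, including large glycosides
#: and phosphorus-bearing polyketides.
DEFAULT_ELEMENT_RANGES: dict[str, tuple[int, int]] = {
    "C": (0, 60),
    "H": (0, 100),
    "N": (0, 10),
    "O": (0, 25),
    "P": (0, 3),
    "S": (0, 3),
}

#: Refuse enumeration when the naive size of the search box exceeds this.
MAX_SEARCH_BOX = 10**8

_HILL_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable formula strings or unknown elements."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition with derived monoisotopic mass and RDBE.

    Parameters
    ----------
    element_counts
        Mapping element symbol -> non-negative integer count.  Zero counts
        are dropped on construction.
    """

    element_counts: tuple[tuple[str, int], ...]

    def __init__(self, element_counts: dict[str, int] | tuple[tuple[str, int], ...]):
        items = dict(element_counts)
        for el, n in items.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0 or n != int(n):
                raise FormulaError(f"negative or non-integer count for {el}: {n}")
        cleaned = tuple(sorted((el, int(n)) for el, n in items.items() if n > 0))
        if not cleaned:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "element_counts", cleaned)

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    def count(self, element: str) -> int:
        return dict(self.element_counts).get(element, 0)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.element_counts)

    @property
    def rdbe(self) -> float:
        c = dict(self.element_counts)
        return (
            c.get("C", 0)
            - c.get("H", 0) / 2.0
            + (c.get("N", 0) + c.get("P", 0)) / 2.0
            + 1.0
        )

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.element_counts)

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        counts = dict(self.element_counts)
        parts: list[str] = []
        order: list[str] = []
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(el for el in counts if el not in ("C", "H"))
        else:
            order = sorted(counts)
        for el in order:
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``C22H24N2O9``.

    A count of 1 may be omitted (``C16H21NO``).  Raises
    :class:`FormulaError` on anything that is not a sequence of element
    symbols with optional integer counts.
    """
    s = text.strip()
    if not s:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _HILL_TOKEN.finditer(s):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {text!r} at position {pos}")
        if not m.group(0):
            break
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(s):
        raise FormulaError(f"unparseable formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic mass (Da) of a formula (string or object)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return formula.monoisotopic_mass


def rdbe(formula: MolecularFormula | str) -> float:
    """Rings-plus-double-bond equivalents: C - H/2 + (N + P)/2 + 1."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return formula.rdbe


def nitrogen_rule_ok(formula: MolecularFormula | str) -> bool:
    """True iff the RDBE is integer-valued.

    For an even-electron neutral molecule over CHNOPS this is equivalent to
    the classical nitrogen rule relating nominal-mass parity to the parity
    of N (+P) count.
    """
    return float(rdbe(formula)).is_integer()


@dataclass(frozen=True)
class FormulaCandidate:
    """One candidate composition for a queried neutral mass."""

    formula: MolecularFormula
    ppm_error: float
    passes_nitrogen_rule: bool
    rank: int = field(default=0, compare=False)


def _search_box_size(ranges: dict[str, tuple[int, int]]) -> int:
    size = 1
    for lo, hi in ranges.values():
        size *= hi - lo + 1
    return size


def enumerate_formulas(
    neutral_mass: float,
    tol_ppm: float = 5.0,
    element_ranges: dict[str, tuple[int, int]] | None = None,
    rdbe_min: float = 0.0,
    rdbe_max: float = 40.0,
    nitrogen_rule: bool = False,
) -> list[FormulaCandidate]:
    """Enumerate all formulas within ``tol_ppm`` of ``neutral_mass``.

    The search is exhaustive over the integer element box: a depth-first
    recursion assigns the heavy elements in descending atomic-mass order
    with lower/upper mass-bound pruning, and hydrogen (the lightest
    element) is resolved last by direct division of the residual mass, so
    no valid combination can be skipped.  Candidates are annotated with the
    nitrogen-rule flag and filtered by it only when ``nitrogen_rule`` is
    enabled; RDBE bounds are always applied.

    Results are sorted by \\|ppm error\\| ascending, ties broken by fewer
    total atoms, then lexicographic Hill string; ranks are 1-based.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    ranges = dict(DEFAULT_ELEMENT_RANGES if element_ranges is None else element_ranges)
    for el in ranges:
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in ranges")
    box = _search_box_size(ranges)
    if box > MAX_SEARCH_BOX:
        raise ValueError(
            f"element ranges imply {box:.2e} combinations "
            f"(> {MAX_SEARCH_BOX:.0e}); narrow the search box"
        )

    tol_da = tol_ppm * 1e-6 * neutral_mass
    lo_target = neutral_mass - tol_da
    hi_target = neutral_mass + tol_da

    # heavy elements, heaviest first; hydrogen handled analytically at the leaf
    heavies = sorted(
        (el for el in ranges if el != "H"),
        key=lambda el: MONOISOTOPIC_MASS[el],
        reverse=True,
    )
    h_lo, h_hi = ranges.get("H", (0, 0))
    m_h = MONOISOTOPIC_MASS["H"]

    out: list[FormulaCandidate] = []
    counts: dict[str, int] = {}

    def recurse(idx: int, mass_so_far: float) -> None:
        if mass_so_far > hi_target:
            return
        if idx == len(heavies):
            residual = neutral_mass - mass_so_far
            # hydrogen counts whose total mass lands inside the window
            n_min = max(h_lo, math.ceil((lo_target - mass_so_far) / m_h - 1e-9))
            n_max = min(h_hi, math.floor((hi_target - mass_so_far) / m_h + 1e-9))
            for n_h in range(n_min, n_max + 1):
                total = mass_so_far + n_h * m_h
                if not (lo_target <= total <= hi_target):
                    continue
                trial = dict(counts)
                if n_h:
                    trial["H"] = n_h
                if not trial:
                    continue
                f = MolecularFormula(trial)
                if not (rdbe_min <= f.rdbe <= rdbe_max):
                    continue
                n_ok = nitrogen_rule_ok(f)
                if nitrogen_rule and not n_ok:
                    continue
                ppm = 1e6 * (neutral_mass - f.monoisotopic_mass) / f.monoisotopic_mass
                out.append(FormulaCandidate(f, ppm, n_ok))
            return
        el = heavies[idx]
        lo, hi = ranges[el]
        m_el = MONOISOTOPIC_MASS[el]
        # prune: even filling the rest of the box with max H cannot reach lo_target
        for n in range(lo, hi + 1):
            new_mass = mass_so_far + n * m_el
            if new_mass > hi_target:
                break
            if n > 0:
                counts[el] = n
            elif el in counts:
                del counts[el]
            recurse(idx + 1, new_mass)
        counts.pop(el, None)

    recurse(0, 0.0)

    out.sort(key=lambda c: (abs(c.ppm_error), c.formula.n_atoms, c.formula.hill()))
    return [
        FormulaCandidate(c.formula, c.ppm_error, c.passes_nitrogen_rule, rank=i + 1)
        for i, c in enumerate(out)
    ]


def enumerate_formulas_bruteforce(
    neutral_mass: float,
    tol_ppm: float,
    element_ranges: dict[str, tuple[int, int]],
    rdbe_min: float = 0.0,
    rdbe_max: float = 40.0,
) -> set[tuple[tuple[str, int], ...]]:
    """Naive nested-loop enumeration over the full element box.

    Intended for small boxes only (tests and sanity checks); returns the
    set of element-count tuples so callers can compare against
    :func:`enumerate_formulas` irrespective of ordering.
    """
    tol_da = tol_ppm * 1e-6 * neutral_mass
    names = sorted(element_ranges)
    axes = [range(lo, hi + 1) for lo, hi in (element_ranges[n] for n in names)]
    hits: set[tuple[tuple[str, int], ...]] = set()
    for combo in itertools.product(*axes):
        if all(n == 0 for n in combo):
            continue
        mass = sum(n * MONOISOTOPIC_MASS[el] for el, n in zip(names, combo))
        if abs(mass - neutral_mass) > tol_da:
            continue
        f = MolecularFormula({el: n for el, n in zip(names, combo) if n > 0})
        if rdbe_min <= f.rdbe <= rdbe_max:
            hits.add(f.element_counts)
    return hits
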