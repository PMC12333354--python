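"""Elemental formulas, monoisotopic masses and singly-charged ion m/z.

Every mass in the package is derived from the monoisotopic atomic masses
in :data:`MONOISOTOPIC_MASS` and the proton mass in :data:`PROTON_MASS`.
Neutral-loss masses (water, carbon monoxide, carbon dioxide) are derived
from the same table rather than stored independently, so there is a single
auditable source of truth for all m/z arithmetic.

Ionisation is modelled as gain or loss of a proton (1.00727646 Da, i.e.
the electron mass is accounted for) at charge 1; all species handled by
this package are singly charged.
"""

from __future__ import annotations

import re
from enum import Enum
from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "FORMULA_H2O",
    "FORMULA_CO",
    "FORMULA_CO2",
    "MASS_H2O",
    "MASS_CO",
    "MASS_CO2",
    "IonMode",
    "ElementalFormula",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
]

#: IUPAC monoisotopic atomic masses (Da), 8 decimal places.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
}

#: Mass of the proton (Da).  Used for [M+H]+ / [M-H]- at charge 1.
PROTON_MASS: float = 1.00727646


class IonMode(Enum):
    """Electrospray polarity: protonated (+) or deprotonated (-) ions."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    @property
    def sign(self) -> int:
        return 1 if self is IonMode.POSITIVE else -1

    @classmethod
    def from_string(cls, text: str) -> "IonMode":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(f"unknown ion mode: {text!r}") from None


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula arithmetic."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula:
    """An element -> count multiset, the unit of all mass computation.

    Counts are strictly positive; elements whose count reaches zero are
    dropped.  Addition and subtraction are element-wise; subtraction that
    would drive any count negative raises :class:`FormulaError`.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        clean: Dict[str, int] = {}
        for element, count in (counts or {}).items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int):
                raise FormulaError(f"count for {element} must be an integer")
            if count < 0:
                raise FormulaError(f"negative count for {element}: {count}")
            if count > 0:
                clean[element] = count
        self._counts = clean

    @property
    def counts(self) -> Dict[str, int]:
        return dict(self._counts)

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self._counts.items())

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self._counts)
        for element, count in other:
            merged[element] = merged.get(element, 0) + count
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self._counts)
        for element, count in other:
            remaining = merged.get(element, 0) - count
            if remaining < 0:
                raise FormulaError(
                    f"subtraction yields negative {element} count "
                    f"({self} - {other})"
                )
            merged[element] = remaining
        return ElementalFormula(merged)

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:
        return f"ElementalFormula({self._counts!r})"


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C29H49NO4"``.

    An omitted count means 1.  Repeated element symbols are summed.
    Raises :class:`FormulaError` on empty input, unknown element symbols
    or text that is not a sequence of element-count tokens.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element = match.group(1)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        count = int(match.group(2)) if match.group(2) else 1
        if count == 0:
            raise FormulaError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)


_HILL_ORDER = {"C": 0, "H": 1}


def format_formula(f: ElementalFormula) -> str:
    """Format in Hill order (C, H, then remaining elements alphabetically).

    Counts of 1 are omitted, matching the notation used for bile-acid and
    amino-acid formulas (e.g. ``C29H49NO4``).  Round-trips with
    :func:`parse_formula`.
    """
    parts = []
    for element in sorted(f.counts, key=lambda e: (_HILL_ORDER.get(e, 2), e)):
        count = f[element]
        parts.append(element if count == 1 else f"{element}{count}")
    return "".join(parts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass (Da): sum of count x atomic monoisotopic mass."""
    return sum(MONOISOTOPIC_MASS[element] * count for element, count in f)


def ion_mz(f: ElementalFormula, mode: IonMode) -> float:
    """m/z of the singly charged [M+H]+ or [M-H]- ion of a neutral formula."""
    return monoisotopic_mass(f) + mode.sign * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    Positive when the observed m/z exceeds the theoretical one.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


# Neutral losses, derived from the constants table (never hard-coded).
FORMULA_H2O = ElementalFormula({"H": 2, "O": 1})
FORMULA_CO = ElementalFormula({"C": 1, "O": 1})
FORMULA_CO2 = ElementalFormula({"C": 1, "O": 2})

MASS_H2O: float = monoisotopic_mass(FORMULA_H2O)
MASS_CO: float = monoisotopic_mass(FORMULA_CO)
MASS_CO2: float = monoisotopic_mass(FORMULA_CO2)
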