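"""Registries of bile-acid cores and nitrogenous acids.

The central attribute of a nitrogenous acid is the position of its amino
group relative to the carboxyl group, because that position determines
the diagnostic neutral loss its protonated form undergoes after release
from a conjugate: acids with the amino group on the alpha carbon lose
H2O+CO (-46 Da) to give an immonium-type ion, while acids with a
terminal amino group distal to the carboxyl lose only H2O (-18 Da).
Positional isomers such as valine / 5-aminovaleric acid, or the three
aminobutyric acids, share one molecular formula and can only be told
apart by this rule.

Registries are data, not code: the packaged CSVs can be copied and
extended by users as new conjugates are discovered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import List, Optional, Union

from .chem import ElementalFormula, FormulaError, parse_formula

__all__ = [
    "AminoPosition",
    "BileAcidCore",
    "NitrogenousAcid",
    "RegistryError",
    "load_cores",
    "load_acids",
    "default_cores",
    "default_acids",
    "packaged_data_path",
]


class RegistryError(ValueError):
    """Raised when a registry CSV is malformed or internally inconsistent."""


class AminoPosition(Enum):
    """Position of the amino group relative to the carboxyl group.

    ``ALPHA``    amino group on the carbon adjacent to the carboxyl
                 (valine, leucine, glycine, 2-aminobutyric acid);
    ``TERMINAL`` amino group at the chain end distal to the carboxyl
                 (4-aminobutyric acid / GABA, 5-aminovaleric acid);
    ``OTHER``    any intermediate position, e.g. beta (3-aminobutyric acid);
    ``NONE``     acids without the standard carboxyl group (taurine).
    """

    ALPHA = "alpha"
    TERMINAL = "terminal"
    OTHER = "other"
    NONE = "none"

    @classmethod
    def from_string(cls, text: str) -> "AminoPosition":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise RegistryError(f"unknown amino position: {text!r}") from None


@dataclass(frozen=True)
class BileAcidCore:
    """A bile-acid backbone available for C24-acyl amidation."""

    name: str
    abbreviation: str
    formula: ElementalFormula
    n_hydroxyl: int
    epimer_of: Optional[str] = None
    reference_rt: Optional[float] = None  # minutes

    def __post_init__(self) -> None:
        if self.n_hydroxyl < 0:
            raise RegistryError(f"{self.abbreviation}: n_hydroxyl must be >= 0")
        extra = set(self.formula.counts) - {"C", "H", "O"}
        if extra:
            raise RegistryError(
                f"{self.abbreviation}: bile-acid core formula may contain "
                f"C, H, O only (found {sorted(extra)})"
            )


@dataclass(frozen=True)
class NitrogenousAcid:
    """An amino acid or related nitrogenous acid available for conjugation."""

    name: str
    formula: ElementalFormula
    amino_position: AminoPosition
    proteinogenic: bool = False
    reference_rt_shift: Optional[float] = None


def _read_rows(path: Union[str, Path], required: List[str]) -> List[dict]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise RegistryError(f"{path}: empty registry file")
        missing = [col for col in required if col not in reader.fieldnames]
        if missing:
            raise RegistryError(f"{path}: missing columns {missing}")
        return list(reader)


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in {"true", "1", "yes"}


def _parse_optional_float(text: str) -> Optional[float]:
    text = (text or "").strip()
    return float(text) if text else None


def load_cores(path: Union[str, Path]) -> List[BileAcidCore]:
    """Load a bile-acid core registry from CSV.

    Required columns: name, abbreviation, formula, n_hydroxyl; optional:
    epimer_of, reference_rt.  Abbreviations must be unique.
    """
    rows = _read_rows(path, ["name", "abbreviation", "formula", "n_hydroxyl"])
    cores: List[BileAcidCore] = []
    seen = set()
    for row in rows:
        abbrev = row["abbreviation"].strip()
        if abbrev in seen:
            raise RegistryError(f"duplicate core abbreviation: {abbrev!r}")
        seen.add(abbrev)
        try:
            formula = parse_formula(row["formula"])
        except FormulaError as exc:
            raise RegistryError(f"core {abbrev!r}: {exc}") from exc
        cores.append(
            BileAcidCore(
                name=row["name"].strip(),
                abbreviation=abbrev,
                formula=formula,
                n_hydroxyl=int(row["n_hydroxyl"]),
                epimer_of=(row.get("epimer_of") or "").strip() or None,
                reference_rt=_parse_optional_float(row.get("reference_rt", "")),
            )
        )
    return cores


def load_acids(path: Union[str, Path]) -> List[NitrogenousAcid]:
    """Load a nitrogenous-acid registry from CSV.

    Required columns: name, formula, amino_position; optional:
    proteinogenic, reference_rt_shift.  Names must be unique; formulas
    need not be (positional isomers deliberately share formulas).
    """
    rows = _read_rows(path, ["name", "formula", "amino_position"])
    acids: List[NitrogenousAcid] = []
    seen = set()
    for row in rows:
        name = row["name"].strip()
        if name in seen:
            raise RegistryError(f"duplicate acid name: {name!r}")
        seen.add(name)
        try:
            formula = parse_formula(row["formula"])
        except FormulaError as exc:
            raise RegistryError(f"acid {name!r}: {exc}") from exc
        acids.append(
            NitrogenousAcid(
                name=name,
                formula=formula,
                amino_position=AminoPosition.from_string(row["amino_position"]),
                proteinogenic=_parse_bool(row.get("proteinogenic", "")),
                reference_rt_shift=_parse_optional_float(
                    row.get("reference_rt_shift", "")
                ),
            )
        )
    return acids


def packaged_data_path(filename: str) -> Path:
    """Path of a data file shipped inside the package."""
    return Path(resources.files("mcba").joinpath("data", filename))  # type: ignore[arg-type]


def default_cores() -> List[BileAcidCore]:
    """The packaged bile-acid core registry (primary and secondary BAs)."""
    return load_cores(packaged_data_path("bile_acid_cores.csv"))


def default_acids() -> List[NitrogenousAcid]:
    """The packaged nitrogenous-acid registry."""
    return load_acids(packaged_data_path("nitrogenous_acids.csv"))
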