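"""Combinatorial candidate library of bile-acid / nitrogenous-acid amides.

Each candidate is the amide condensation product of one bile-acid core
and one nitrogenous acid at the C24 acyl site: the conjugate formula is
``core + acid - H2O``.  Candidates sharing a molecular formula form an
isobaric group — they share both ion m/z values and can only be told
apart downstream by diagnostic MS/MS fragments, so the library never
merges them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .building_blocks import BileAcidCore, NitrogenousAcid, RegistryError
from .chem import (
    FORMULA_H2O,
    ElementalFormula,
    IonMode,
    format_formula,
    ion_mz,
    monoisotopic_mass,
)

__all__ = [
    "MCBACandidate",
    "IsobaricGroup",
    "conjugate_formula",
    "build_library",
    "write_library_tsv",
    "read_library_tsv",
]

AMIDE_BOND = "amide-C24"


@dataclass(frozen=True)
class MCBACandidate:
    """One core x acid amide with its conjugate formula and ion m/z values."""

    core: BileAcidCore
    acid: NitrogenousAcid
    conjugate_formula: ElementalFormula
    neutral_mass: float
    mz_pos: float
    mz_neg: float
    bond: str = AMIDE_BOND

    @property
    def name(self) -> str:
        return f"{self.acid.name}-{self.core.abbreviation}"

    def mz(self, mode: IonMode) -> float:
        return self.mz_pos if mode is IonMode.POSITIVE else self.mz_neg


@dataclass(frozen=True)
class IsobaricGroup:
    """All candidates sharing one conjugate formula (hence one precursor m/z)."""

    formula: ElementalFormula
    members: Tuple[MCBACandidate, ...]


def conjugate_formula(
    core: BileAcidCore, acid: NitrogenousAcid
) -> ElementalFormula:
    """Formula of the amide condensation product: core + acid - H2O."""
    return core.formula + acid.formula - FORMULA_H2O


def _make_candidate(core: BileAcidCore, acid: NitrogenousAcid) -> MCBACandidate:
    formula = conjugate_formula(core, acid)
    mass = monoisotopic_mass(formula)
    return MCBACandidate(
        core=core,
        acid=acid,
        conjugate_formula=formula,
        neutral_mass=mass,
        mz_pos=ion_mz(formula, IonMode.POSITIVE),
        mz_neg=ion_mz(formula, IonMode.NEGATIVE),
    )


def build_library(
    cores: Sequence[BileAcidCore], acids: Sequence[NitrogenousAcid]
) -> Tuple[List[MCBACandidate], List[IsobaricGroup]]:
    """Enumerate every core x acid pair into candidates and isobaric groups.

    Exactly ``len(cores) * len(acids)`` candidates are produced, in
    deterministic order (core abbreviation, then acid name); candidates
    with identical formulas are never deduplicated.  Isobaric groups are
    ordered by neutral mass.
    """
    candidates = [
        _make_candidate(core, acid)
        for core in sorted(cores, key=lambda c: c.abbreviation)
        for acid in sorted(acids, key=lambda a: a.name)
    ]
    by_formula: Dict[ElementalFormula, List[MCBACandidate]] = {}
    for cand in candidates:
        by_formula.setdefault(cand.conjugate_formula, []).append(cand)
    groups = [
        IsobaricGroup(formula=f, members=tuple(members))
        for f, members in sorted(
            by_formula.items(), key=lambda item: monoisotopic_mass(item[0])
        )
    ]
    return candidates, groups


_LIBRARY_COLUMNS = [
    "core",
    "acid",
    "formula",
    "neutral_mass",
    "mz_pos",
    "mz_neg",
    "amino_position",
]


def write_library_tsv(
    candidates: Iterable[MCBACandidate], path: Union[str, Path]
) -> None:
    """Write candidates to TSV (core, acid, formula, masses, amino position)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_LIBRARY_COLUMNS)
        for cand in candidates:
            writer.writerow(
                [
                    cand.core.abbreviation,
                    cand.acid.name,
                    format_formula(cand.conjugate_formula),
                    f"{cand.neutral_mass:.6f}",
                    f"{cand.mz_pos:.6f}",
                    f"{cand.mz_neg:.6f}",
                    cand.acid.amino_position.value,
                ]
            )


def read_library_tsv(
    path: Union[str, Path],
    cores: Sequence[BileAcidCore],
    acids: Sequence[NitrogenousAcid],
) -> List[MCBACandidate]:
    """Read a library TSV back, resolving rows against the given registries.

    The TSV stores only identifiers; core/acid records (formulas, hydroxyl
    counts, amino positions) come from the registries, and each row is
    re-derived so that a stale or hand-edited TSV cannot inject
    inconsistent masses.
    """
    core_by_abbrev = {c.abbreviation: c for c in cores}
    acid_by_name = {a.name: a for a in acids}
    path = Path(path)
    candidates: List[MCBACandidate] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            core = core_by_abbrev.get(row["core"])
            acid = acid_by_name.get(row["acid"])
            if core is None:
                raise RegistryError(f"unknown core in library: {row['core']!r}")
            if acid is None:
                raise RegistryError(f"unknown acid in library: {row['acid']!r}")
            cand = _make_candidate(core, acid)
            if format_formula(cand.conjugate_formula) != row["formula"]:
                raise RegistryError(
                    f"library row {row['core']}/{row['acid']}: formula "
                    f"{row['formula']} does not match registries"
                )
            candidates.append(cand)
    return candidates
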