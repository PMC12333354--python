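#!/usr/bin/env python
"""Enumerate the combinatorial MCBA candidate space.

Builds every amide of the packaged bile-acid cores with the packaged
nitrogenous acids, writes the library TSV, and reports the isobaric
groups that make positive-mode diagnostics necessary in the first
place (e.g. valine vs 5-aminovaleric conjugates at one shared m/z).
"""

from pathlib import Path

from mcba.building_blocks import default_acids, default_cores
from mcba.chem import format_formula
from mcba.library import build_library, write_library_tsv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cores, acids = default_cores(), default_acids()
    candidates, groups = build_library(cores, acids)
    OUT.mkdir(exist_ok=True)
    write_library_tsv(candidates, OUT / "library.tsv")
    print(
        f"{len(cores)} cores x {len(acids)} acids -> {len(candidates)} "
        f"candidates in {len(groups)} isobaric groups"
    )
    ambiguous = [g for g in groups if len(g.members) > 2]
    print(f"{len(ambiguous)} groups have >2 members (isomer ambiguity):")
    for group in ambiguous:
        members = ", ".join(
            f"{c.acid.name}+{c.core.abbreviation}" for c in group.members
        )
        print(
            f"  {format_formula(group.formula)} "
            f"[M+H]+ {group.members[0].mz_pos:.4f}: {members}"
        )
    print(f"library written to {OUT / 'library.tsv'}")


if __name__ == "__main__":
    main()
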