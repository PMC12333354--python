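"""Predicted MS/MS fragments of MCBA candidates, per polarity.

Negative mode ([M-H]-) confirms the presence of a conjugate: the amide
bond cleaves and the nitrogenous acid leaves as a deprotonated residue
anion, accompanied by CO2 loss from the precursor.  All positional
isomers of the acid give identical negative-mode spectra.

Positive mode ([M+H]+) is where isomers separate.  The protonated
nitrogenous acid is released intact and then fragments a second time,
and the neutral it loses depends on where its amino group sits:

* amino group on the alpha carbon  -> loss of H2O + CO (-46.0055 Da),
  an immonium-type ion;
* amino group at the chain terminus -> loss of H2O only (-18.0106 Da).

The two hypothetical diagnostics for any acid are exactly one CO
(27.9949 Da) apart, so a matcher can test both hypotheses on an unknown
spectrum without ambiguity.  The steroid backbone contributes a ladder
of water-loss fragments (e.g. m/z 359.29 / 341.28 / 323.27 for
lithocholic-acid conjugates) shared by all isomers.

Relative intensities are deliberately not predicted; a fragment set is
a set, not a spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .building_blocks import AminoPosition, NitrogenousAcid
from .chem import (
    MASS_CO,
    MASS_CO2,
    MASS_H2O,
    PROTON_MASS,
    IonMode,
    monoisotopic_mass,
)
from .library import MCBACandidate

__all__ = [
    "PredictedFragment",
    "predict_negative",
    "predict_positive",
    "predict_fragments",
    "diagnostic_pair",
]

DIAGNOSTIC_LABELS = {"diagnostic_alpha", "diagnostic_terminal"}


@dataclass(frozen=True)
class PredictedFragment:
    """One predicted fragment m/z with a descriptive label."""

    mz: float
    polarity: IonMode
    label: str
    diagnostic: bool = False

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"fragment m/z must be positive, got {self.mz}")
        if self.diagnostic and self.label not in DIAGNOSTIC_LABELS:
            raise ValueError(f"label {self.label!r} cannot be diagnostic")


def predict_negative(candidate: MCBACandidate) -> List[PredictedFragment]:
    """Negative-mode fragments: precursor, acid residue anion, CO2 loss.

    The residue (deprotonated free acid, e.g. m/z 116.0717 for valine
    conjugates) is shared by all positional isomers of the acid, which is
    why negative mode confirms conjugation but cannot classify it.
    """
    mode = IonMode.NEGATIVE
    precursor = candidate.mz_neg
    residue = monoisotopic_mass(candidate.acid.formula) - PROTON_MASS
    return [
        PredictedFragment(precursor, mode, "precursor"),
        PredictedFragment(residue, mode, "residue"),
        PredictedFragment(precursor - MASS_CO2, mode, "co2_loss"),
    ]


def predict_positive(candidate: MCBACandidate) -> List[PredictedFragment]:
    """Positive-mode fragments including the amino-position diagnostic.

    Contains [M+H]+, its water loss, the steroid backbone water-loss
    ladder [core+H - k*H2O]+ for k = 1..n_hydroxyl+2 (the amide cleavage
    itself consumes one water equivalent, so a mono-hydroxyl core shows
    three effective losses), the released protonated acid, and exactly
    one diagnostic ion when the acid's amino position is alpha (-H2O-CO)
    or terminal (-H2O).  Acids with amino position ``other`` or ``none``
    get no diagnostic: no fragmentation rule is asserted for them.
    """
    mode = IonMode.POSITIVE
    precursor = candidate.mz_pos
    frags = [
        PredictedFragment(precursor, mode, "precursor"),
        PredictedFragment(precursor - MASS_H2O, mode, "water_loss"),
    ]
    core_protonated = monoisotopic_mass(candidate.core.formula) + PROTON_MASS
    for k in range(1, candidate.core.n_hydroxyl + 3):
        frags.append(
            PredictedFragment(core_protonated - k * MASS_H2O, mode, f"backbone_{k}")
        )
    acid_protonated = monoisotopic_mass(candidate.acid.formula) + PROTON_MASS
    frags.append(PredictedFragment(acid_protonated, mode, "protonated_acid"))
    alpha_mz, terminal_mz = diagnostic_pair(candidate.acid)
    position = candidate.acid.amino_position
    if position is AminoPosition.ALPHA:
        frags.append(
            PredictedFragment(alpha_mz, mode, "diagnostic_alpha", diagnostic=True)
        )
    elif position is AminoPosition.TERMINAL:
        frags.append(
            PredictedFragment(
                terminal_mz, mode, "diagnostic_terminal", diagnostic=True
            )
        )
    return frags


def predict_fragments(
    candidate: MCBACandidate, mode: IonMode
) -> List[PredictedFragment]:
    """Fragment set for the requested polarity (pure function of inputs)."""
    if mode is IonMode.NEGATIVE:
        return predict_negative(candidate)
    return predict_positive(candidate)


def diagnostic_pair(
    acid: NitrogenousAcid,
) -> Tuple[Optional[float], Optional[float]]:
    """Both hypothetical diagnostic m/z values for an acid.

    Returns ``(alpha_mz, terminal_mz)``: the protonated free acid minus
    H2O+CO and minus H2O respectively.  Both are computed regardless of
    the registry's amino position, so a classifier can test the two
    hypotheses on an unknown and let the spectrum decide.
    """
    protonated = monoisotopic_mass(acid.formula) + PROTON_MASS
    return protonated - MASS_H2O - MASS_CO, protonated - MASS_H2O
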