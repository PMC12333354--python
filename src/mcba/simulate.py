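"""Synthetic QTOF-like MS/MS spectra with known ground truth.

The generator emulates the statistical structure of the spectra the
matcher is designed for: predicted fragments of a library candidate,
perturbed by Gaussian mass error in two regimes (absolute mDa below
150 Da, ppm above — the same regimes as the matching tolerances),
thinned by random fragment dropout (the precursor and the diagnostic
ion always survive, as they do in practice at the collision energies
where these spectra are acquired), and contaminated with uniformly
placed noise peaks.  Intensities are log-normal, since reference
fragment tables print none and classification must not depend on the
intensity scale.

A fixed seed makes files byte-identical; recovery of the generating
acid's amino position against the simulated truth is the package's
end-to-end self-check.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .building_blocks import AminoPosition
from .chem import IonMode
from .fragments import predict_fragments
from .library import MCBACandidate
from .matching import AnnotationResult, top_annotations
from .spectra import Spectrum, write_mgf

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "RecoveryReport",
    "simulate_spectrum",
    "simulate_dataset",
    "write_truth_tsv",
    "read_truth_tsv",
    "evaluate_recovery",
]

CLASS_LABELS = ("alpha", "terminal", "ambiguous", "unclassified")


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model and size of a simulated dataset.

    Mass-error magnitudes default to what a well-calibrated QTOF shows:
    ~2 ppm on precursors, ~3 ppm on fragments above 150 Da and up to a
    few mDa on small immonium-region ions.  ``force_diagnostic_dropout``
    removes the diagnostic ion from every spectrum — the negative
    control for false diagnostic matches from noise alone.
    """

    n_per_candidate: int = 1
    polarity: IonMode = IonMode.POSITIVE
    precursor_ppm_sigma: float = 2.0
    frag_ppm_sigma: float = 3.0  # at/above low_mass_cutoff
    frag_mda_sigma: float = 4.0  # below low_mass_cutoff, milli-Da
    low_mass_cutoff: float = 150.0
    dropout_prob: float = 0.2
    n_noise_peaks: int = 5
    noise_mz_min: float = 50.0
    noise_mz_max: float = 1100.0
    intensity_meanlog: float = 0.0
    intensity_sdlog: float = 1.0
    force_diagnostic_dropout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("precursor_ppm_sigma", "frag_ppm_sigma", "frag_mda_sigma",
                     "intensity_sdlog"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.n_per_candidate < 0 or self.n_noise_peaks < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_mz_min >= self.noise_mz_max:
            raise ValueError("noise_mz_min must be < noise_mz_max")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one simulated spectrum."""

    spectrum_id: str
    core: str
    acid: str
    amino_position: AminoPosition

    @property
    def expected_classification(self) -> str:
        """The classification a perfect pipeline should emit.

        Acids with amino position ``other`` or ``none`` carry no
        diagnostic rule, so the correct call for them is
        ``unclassified``.
        """
        if self.amino_position in (AminoPosition.ALPHA, AminoPosition.TERMINAL):
            return self.amino_position.value
        return "unclassified"


def _mass_error(rng: np.random.Generator, mz: float, cfg: SimulationConfig) -> float:
    if mz < cfg.low_mass_cutoff:
        return float(rng.normal(0.0, cfg.frag_mda_sigma * 1e-3))
    return float(rng.normal(0.0, cfg.frag_ppm_sigma * mz * 1e-6))


def _intensity(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    return float(rng.lognormal(cfg.intensity_meanlog, cfg.intensity_sdlog))


def simulate_spectrum(
    candidate: MCBACandidate,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    identifier: Optional[str] = None,
) -> Tuple[Spectrum, TruthRecord]:
    """One noisy spectrum of a candidate, with its truth record.

    Every non-precursor, non-diagnostic predicted fragment is dropped
    with probability ``dropout_prob``; surviving peaks get the
    regime-appropriate Gaussian mass error; ``n_noise_peaks`` uniform
    noise peaks are added; the reported precursor m/z is perturbed by
    ``precursor_ppm_sigma``.
    """
    if identifier is None:
        identifier = f"sim_{candidate.acid.name}_{candidate.core.abbreviation}"
    predicted = predict_fragments(candidate, cfg.polarity)
    mzs: List[float] = []
    intensities: List[float] = []
    for frag in predicted:
        protected = frag.label == "precursor" or frag.diagnostic
        if frag.diagnostic and cfg.force_diagnostic_dropout:
            continue
        if not protected and rng.uniform() < cfg.dropout_prob:
            continue
        mzs.append(frag.mz + _mass_error(rng, frag.mz, cfg))
        intensities.append(_intensity(rng, cfg))
    for _ in range(cfg.n_noise_peaks):
        mzs.append(float(rng.uniform(cfg.noise_mz_min, cfg.noise_mz_max)))
        intensities.append(_intensity(rng, cfg))
    true_precursor = candidate.mz(cfg.polarity)
    precursor_mz = true_precursor * (
        1.0 + float(rng.normal(0.0, cfg.precursor_ppm_sigma)) * 1e-6
    )
    spectrum = Spectrum(
        identifier=identifier,
        precursor_mz=precursor_mz,
        polarity=cfg.polarity,
        mz=np.array(mzs),
        intensity=np.array(intensities),
    )
    truth = TruthRecord(
        spectrum_id=identifier,
        core=candidate.core.abbreviation,
        acid=candidate.acid.name,
        amino_position=candidate.acid.amino_position,
    )
    return spectrum, truth


def simulate_dataset(
    library: Sequence[MCBACandidate],
    cfg: SimulationConfig,
    mgf_path: Optional[Union[str, Path]] = None,
    truth_path: Optional[Union[str, Path]] = None,
) -> Tuple[List[Spectrum], List[TruthRecord]]:
    """``n_per_candidate`` spectra per library candidate, seed-determined.

    When paths are given, the spectra are written as MGF and the truth
    as TSV; identical (library, cfg) pairs produce byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    spectra: List[Spectrum] = []
    truths: List[TruthRecord] = []
    counter = 0
    for rep in range(cfg.n_per_candidate):
        for candidate in library:
            identifier = (
                f"s{counter:04d}_{candidate.acid.name}"
                f"_{candidate.core.abbreviation}_r{rep}"
            ).replace(" ", "_")
            spectrum, truth = simulate_spectrum(candidate, cfg, rng, identifier)
            spectra.append(spectrum)
            truths.append(truth)
            counter += 1
    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if truth_path is not None:
        write_truth_tsv(truths, truth_path)
    return spectra, truths


def write_truth_tsv(truths: Sequence[TruthRecord], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["spectrum_id", "core", "acid", "amino_position"])
        for t in truths:
            writer.writerow([t.spectrum_id, t.core, t.acid, t.amino_position.value])


def read_truth_tsv(path: Union[str, Path]) -> List[TruthRecord]:
    with Path(path).open(newline="", encoding="utf-8") as handle:
        return [
            TruthRecord(
                spectrum_id=row["spectrum_id"],
                core=row["core"],
                acid=row["acid"],
                amino_position=AminoPosition(row["amino_position"]),
            )
            for row in csv.DictReader(handle, delimiter="\t")
        ]


@dataclass
class RecoveryReport:
    """Classification-recovery summary against simulated ground truth."""

    accuracy: float
    per_class: Dict[str, float]
    confusion: pd.DataFrame  # rows: truth amino position; cols: predicted class
    n: int


def evaluate_recovery(
    annotations: Dict[str, List[AnnotationResult]],
    truths: Sequence[TruthRecord],
) -> RecoveryReport:
    """Fraction of spectra whose top-scoring classification matches truth.

    ``annotations`` maps spectrum id to annotation results (best first,
    as produced by :func:`mcba.matching.annotate_spectra`); a spectrum
    with no results counts as ``unclassified``.  Truth ids must match
    the annotation ids exactly.
    """
    truth_by_id = {t.spectrum_id: t for t in truths}
    if set(truth_by_id) != set(annotations):
        missing = set(truth_by_id) ^ set(annotations)
        raise ValueError(f"annotation/truth id mismatch: {sorted(missing)[:5]} ...")
    tops = top_annotations(annotations)
    positions = sorted({t.amino_position.value for t in truths})
    confusion = pd.DataFrame(
        0, index=positions, columns=list(CLASS_LABELS), dtype=int
    )
    hits: Dict[str, List[bool]] = {}
    for sid, truth in truth_by_id.items():
        top = tops[sid]
        predicted = top.classification if top else "unclassified"
        confusion.loc[truth.amino_position.value, predicted] += 1
        hits.setdefault(truth.amino_position.value, []).append(
            predicted == truth.expected_classification
        )
    per_class = {pos: float(np.mean(flags)) for pos, flags in hits.items()}
    all_flags = [flag for flags in hits.values() for flag in flags]
    return RecoveryReport(
        accuracy=float(np.mean(all_flags)) if all_flags else 0.0,
        per_class=per_class,
        confusion=confusion,
        n=len(all_flags),
    )
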