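"""Peak-list I/O: MGF and CSV spectra, packaged fixtures, annotation tables.

MGF (Mascot Generic Format) is the exchange format: text, ubiquitous and
adequate at desk scale.  The dialect used here is PEPMASS with a single
value, CHARGE ``1+`` / ``1-`` (polarity is taken from the charge sign;
multiply charged ions are rejected), optional RTINSECONDS, and TITLE as
the spectrum identifier.  Reading goes through :mod:`pyteomics.mgf`;
writing is done directly so the dialect is fixed.

The package ships two reference fixtures transcribed from published
identification tables: ten primary/secondary bile acids measured in
negative mode (observed [M-H]-, printed ppm error and fragment lists)
and thirteen MCBAs measured in positive mode (observed [M+H]+ and
fragment lists, with the isomer-diagnostic ion marked).  Fixture peak
intensities are uniform (1.0) because the source tables print none.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from pyteomics import mgf as _pymgf

from .building_blocks import packaged_data_path
from .chem import ElementalFormula, IonMode, parse_formula

__all__ = [
    "Spectrum",
    "SpectrumError",
    "Table1Record",
    "read_mgf",
    "write_mgf",
    "read_peaklist_csv",
    "load_table_fixtures",
    "write_annotations",
    "read_annotations",
]


class SpectrumError(ValueError):
    """Raised for malformed spectrum files or invalid peak lists."""


@dataclass
class Spectrum:
    """An MS/MS peak list with precursor m/z and polarity.

    Peaks are stored sorted ascending by m/z; only that ordering is
    normative (a spectrum is an unordered physical measurement).
    """

    identifier: str
    precursor_mz: float
    polarity: IonMode
    mz: np.ndarray
    intensity: np.ndarray
    rt: Optional[float] = None  # minutes
    collision_energy: Optional[float] = None  # eV
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectrumError("mz and intensity must be 1-D arrays of equal length")
        if self.precursor_mz <= 0:
            raise SpectrumError(f"precursor m/z must be positive, got {self.precursor_mz}")
        if np.any(self.intensity < 0):
            raise SpectrumError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class Table1Record:
    """One bile-acid reference row: observed [M-H]-, printed ppm, fragments."""

    identifier: str
    name: str
    abbreviation: str
    formula: ElementalFormula
    mz_observed: float
    ppm_printed: float
    rt: Optional[float]
    fragments: Tuple[float, ...]
    collision_energy: Optional[float]


def _charge_to_polarity(charge: int) -> IonMode:
    if charge == 1:
        return IonMode.POSITIVE
    if charge == -1:
        return IonMode.NEGATIVE
    raise SpectrumError(f"only singly charged ions are supported, got charge {charge}")


def read_mgf(path: Union[str, Path]) -> List[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects.

    Polarity comes from the CHARGE sign; RTINSECONDS is converted to
    minutes.  Raises :class:`SpectrumError` for a missing PEPMASS or a
    charge magnitude other than 1.
    """
    path = Path(path)
    spectra: List[Spectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1) as reader:
        for index, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise SpectrumError(f"{path}: spectrum {index} has no PEPMASS")
            charges = params.get("charge")
            if not charges:
                raise SpectrumError(f"{path}: spectrum {index} has no CHARGE")
            polarity = _charge_to_polarity(int(charges[0]))
            rt_s = params.get("rtinseconds")
            metadata = {
                k: v
                for k, v in params.items()
                if k not in {"pepmass", "charge", "rtinseconds", "title"}
            }
            spectra.append(
                Spectrum(
                    identifier=str(params.get("title", f"spectrum_{index}")),
                    precursor_mz=float(pepmass[0]),
                    polarity=polarity,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    rt=float(rt_s) / 60.0 if rt_s is not None else None,
                    metadata=metadata,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: Union[str, Path]) -> None:
    """Write spectra in the package's MGF dialect (CHARGE 1+/1-)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        for spectrum in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={spectrum.identifier}\n")
            handle.write(f"PEPMASS={spectrum.precursor_mz:.6f}\n")
            sign = "+" if spectrum.polarity is IonMode.POSITIVE else "-"
            handle.write(f"CHARGE=1{sign}\n")
            if spectrum.rt is not None:
                handle.write(f"RTINSECONDS={spectrum.rt * 60.0:.3f}\n")
            for mz, intensity in zip(spectrum.mz, spectrum.intensity):
                handle.write(f"{mz:.6f} {intensity:.6g}\n")
            handle.write("END IONS\n")


def read_peaklist_csv(path: Union[str, Path]) -> Spectrum:
    """Read a two-column peak list CSV (mz, intensity).

    Metadata travel as ``# key=value`` comment lines before the header;
    ``precursor_mz`` and ``polarity`` are required, ``identifier``,
    ``rt_min`` and ``collision_energy`` optional.
    """
    path = Path(path)
    meta: Dict[str, str] = {}
    rows: List[Tuple[float, float]] = []
    with path.open(encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("#").strip().partition("=")
                meta[key.strip()] = value.strip()
                continue
            if line.lower().replace(" ", "").startswith("mz,"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumError(f"{path}: malformed peak line {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if "precursor_mz" not in meta or "polarity" not in meta:
        raise SpectrumError(
            f"{path}: peak-list CSV needs '# precursor_mz=' and '# polarity=' headers"
        )
    mz, intensity = (np.array(col) for col in zip(*rows)) if rows else (
        np.empty(0),
        np.empty(0),
    )
    return Spectrum(
        identifier=meta.get("identifier", path.stem),
        precursor_mz=float(meta["precursor_mz"]),
        polarity=IonMode.from_string(meta["polarity"]),
        mz=mz,
        intensity=intensity,
        rt=float(meta["rt_min"]) if "rt_min" in meta else None,
        collision_energy=float(meta["collision_energy"])
        if "collision_energy" in meta
        else None,
    )


def _parse_fragment_field(text: str) -> Tuple[Tuple[float, ...], Optional[float]]:
    """Split a ';'-separated fragment list; '*' marks the diagnostic ion."""
    values: List[float] = []
    diagnostic: Optional[float] = None
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        if token.startswith("*"):
            diagnostic = float(token[1:])
            values.append(diagnostic)
        else:
            values.append(float(token))
    return tuple(values), diagnostic


def load_table_fixtures() -> Tuple[List[Table1Record], List[Spectrum]]:
    """Load the packaged reference tables.

    Returns ten negative-mode bile-acid records and thirteen
    positive-mode MCBA spectra (precursor = printed [M+H]+, peaks =
    printed fragments at uniform intensity 1.0; the marked diagnostic
    ion is kept as ``metadata['diagnostic_mz']``).  Raises
    :class:`SpectrumError` if either count is off — the fixtures are
    immutable reference data.
    """
    table1: List[Table1Record] = []
    with packaged_data_path("table1_bile_acids.csv").open(
        newline="", encoding="utf-8"
    ) as handle:
        for row in csv.DictReader(handle):
            fragments, _ = _parse_fragment_field(row["fragments"])
            table1.append(
                Table1Record(
                    identifier=row["id"],
                    name=row["name"],
                    abbreviation=row["abbreviation"],
                    formula=parse_formula(row["formula"]),
                    mz_observed=float(row["mz_observed"]),
                    ppm_printed=float(row["ppm_printed"]),
                    rt=float(row["rt_min"]) if row["rt_min"] else None,
                    fragments=fragments,
                    collision_energy=float(row["collision_energy"])
                    if row["collision_energy"]
                    else None,
                )
            )

    table2: List[Spectrum] = []
    with packaged_data_path("table2_mcbas.csv").open(
        newline="", encoding="utf-8"
    ) as handle:
        for row in csv.DictReader(handle):
            fragments, diagnostic = _parse_fragment_field(row["fragments"])
            table2.append(
                Spectrum(
                    identifier=row["id"],
                    precursor_mz=float(row["mz_observed"]),
                    polarity=IonMode.POSITIVE,
                    mz=np.array(fragments),
                    intensity=np.ones(len(fragments)),
                    rt=float(row["rt_min"]) if row["rt_min"] else None,
                    collision_energy=float(row["collision_energy"])
                    if row["collision_energy"]
                    else None,
                    metadata={
                        "name": row["name"],
                        "formula": row["formula"],
                        "ppm_printed": float(row["ppm_printed"]),
                        "diagnostic_mz": diagnostic,
                    },
                )
            )

    if len(table1) != 10 or len(table2) != 13:
        raise SpectrumError(
            f"fixture integrity check failed: expected 10 and 13 records, "
            f"got {len(table1)} and {len(table2)}"
        )
    return table1, table2


_ANNOTATION_COLUMNS = [
    "spectrum_id",
    "core",
    "acid",
    "formula",
    "precursor_ppm",
    "n_matched",
    "diagnostic_matched",
    "classification",
    "score",
    "confirmed",
]


def write_annotations(results: Sequence, path: Union[str, Path]) -> None:
    """Write annotation results as a TSV, one row per (spectrum, candidate).

    Rows come out in the order given (callers sort deterministically);
    ppm and score are rounded to 2 and 4 decimals for output, full
    precision being an in-memory concern.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.spectrum_id,
                    r.candidate.core.abbreviation,
                    r.candidate.acid.name,
                    str(r.candidate.conjugate_formula),
                    f"{r.precursor_ppm:.2f}",
                    len(r.matched),
                    r.diagnostic_matched,
                    r.classification,
                    f"{r.score:.4f}",
                    str(r.confirmed).lower(),
                ]
            )


def read_annotations(path: Union[str, Path]):
    """Read an annotation TSV back as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
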