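"""Precursor matching, fragment annotation and amino-position classification.

The identification procedure mirrors how MCBAs are confirmed in
practice:

1. precursor match — every library candidate whose ion m/z (in the
   spectrum's polarity) lies within a ppm tolerance of the precursor is
   retained, isobaric candidates included;
2. fragment annotation — each predicted fragment is greedily assigned
   to the nearest unconsumed observed peak within tolerance;
3. classification — both diagnostic hypotheses (protonated acid -H2O-CO
   for an alpha amino group, -H2O for a terminal one) are tested against
   the spectrum, and the one that matches decides the class.

Fragment tolerance runs in two regimes: an absolute window (default
20 mDa) below 150 Da, where QTOF calibration of small immonium-region
ions drifts by up to ~10 mDa, and a ppm window above, where backbone
ions are accurate to <1 mDa.  The two diagnostic hypotheses sit ~28 Da
apart (one CO), so even the generous low-mass window cannot confuse
them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .building_blocks import AminoPosition
from .chem import IonMode, ppm_error
from .fragments import DIAGNOSTIC_LABELS, diagnostic_pair, predict_fragments
from .library import MCBACandidate
from .spectra import Spectrum

__all__ = [
    "MatchConfig",
    "MatchedFragment",
    "AnnotationResult",
    "match_precursor",
    "annotate",
    "classify_amino_position",
    "score",
    "annotate_spectra",
    "top_annotations",
    "classification_census",
]

#: Score multiplier for candidates whose registry amino position
#: contradicts the spectrum's diagnostic evidence.
DEMOTION_FACTOR = 0.5


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances and thresholds of the matching procedure.

    ``precursor_tol_ppm``     precursor window (ppm);
    ``frag_tol_low_da``       absolute fragment window below the cutoff (Da);
    ``frag_tol_ppm``          relative fragment window at/above the cutoff;
    ``low_mass_cutoff``       regime boundary (Da);
    ``min_fragments_for_id``  matched fragments needed to call a candidate
                              confirmed (a precursor match alone never is).
    """

    precursor_tol_ppm: float = 10.0
    frag_tol_low_da: float = 0.02
    frag_tol_ppm: float = 10.0
    low_mass_cutoff: float = 150.0
    min_fragments_for_id: int = 2

    def __post_init__(self) -> None:
        for name in ("precursor_tol_ppm", "frag_tol_low_da", "frag_tol_ppm",
                     "low_mass_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_fragments_for_id < 1:
            raise ValueError("min_fragments_for_id must be >= 1")

    def fragment_tolerance_da(self, mz: float) -> float:
        """Absolute matching window (Da) for a predicted fragment m/z."""
        if mz < self.low_mass_cutoff:
            return self.frag_tol_low_da
        return mz * self.frag_tol_ppm * 1e-6


@dataclass(frozen=True)
class MatchedFragment:
    """One predicted fragment assigned to one observed peak."""

    label: str
    predicted_mz: float
    observed_mz: float
    delta: float  # observed - predicted, Da


@dataclass
class AnnotationResult:
    """Evidence for one candidate against one spectrum."""

    spectrum_id: str
    candidate: MCBACandidate
    precursor_ppm: float
    matched: List[MatchedFragment]
    n_predicted: int
    diagnostic_matched: str  # alpha | terminal | both | none
    classification: str  # alpha | terminal | ambiguous | unclassified
    score: float
    confirmed: bool
    demoted: bool = False
    # intensities of the peaks that matched each diagnostic hypothesis
    alpha_intensity: Optional[float] = None
    terminal_intensity: Optional[float] = None


def match_precursor(
    spectrum: Spectrum,
    library: Sequence[MCBACandidate],
    cfg: MatchConfig = MatchConfig(),
) -> List[MCBACandidate]:
    """All candidates whose ion m/z matches the precursor within tolerance.

    Isobaric candidates are all returned; an empty list is a valid
    result.
    """
    return [
        cand
        for cand in library
        if abs(ppm_error(spectrum.precursor_mz, cand.mz(spectrum.polarity)))
        <= cfg.precursor_tol_ppm
    ]


def _greedy_assign(
    predicted: Sequence, spectrum: Spectrum, cfg: MatchConfig
) -> List[MatchedFragment]:
    """Assign predicted fragments to observed peaks, smallest |delta| first.

    Each observed peak supports at most one predicted fragment (and vice
    versa), so a single peak cannot double-count as two diagnostics.
    """
    pairs: List[Tuple[float, int, int]] = []
    for p_idx, frag in enumerate(predicted):
        tol = cfg.fragment_tolerance_da(frag.mz)
        deltas = spectrum.mz - frag.mz
        for o_idx in np.nonzero(np.abs(deltas) <= tol)[0]:
            pairs.append((abs(float(deltas[o_idx])), p_idx, int(o_idx)))
    pairs.sort()
    used_pred: set = set()
    used_obs: set = set()
    matches: List[MatchedFragment] = []
    for _, p_idx, o_idx in pairs:
        if p_idx in used_pred or o_idx in used_obs:
            continue
        used_pred.add(p_idx)
        used_obs.add(o_idx)
        frag = predicted[p_idx]
        obs = float(spectrum.mz[o_idx])
        matches.append(
            MatchedFragment(frag.label, frag.mz, obs, obs - frag.mz)
        )
    matches.sort(key=lambda m: m.predicted_mz)
    return matches


def _nearest_peak(
    spectrum: Spectrum, mz: float, cfg: MatchConfig
) -> Optional[Tuple[float, float]]:
    """Nearest observed (mz, intensity) within tolerance of ``mz``, if any."""
    if len(spectrum) == 0:
        return None
    deltas = np.abs(spectrum.mz - mz)
    idx = int(np.argmin(deltas))
    if deltas[idx] <= cfg.fragment_tolerance_da(mz):
        return float(spectrum.mz[idx]), float(spectrum.intensity[idx])
    return None


def classify_amino_position(result: AnnotationResult) -> str:
    """Amino-position class from the diagnostic evidence in a result.

    ``alpha`` if only the -H2O-CO diagnostic matched, ``terminal`` if
    only the -H2O diagnostic matched.  When both matched, the tie is
    broken by the higher matched-peak intensity if intensities are
    informative, else ``ambiguous`` stands.  ``unclassified`` when
    neither matched.
    """
    dm = result.diagnostic_matched
    if dm == "alpha":
        return "alpha"
    if dm == "terminal":
        return "terminal"
    if dm == "both":
        a, t = result.alpha_intensity, result.terminal_intensity
        if a is not None and t is not None and a != t:
            return "alpha" if a > t else "terminal"
        return "ambiguous"
    return "unclassified"


def score(result: AnnotationResult) -> float:
    """Evidence score in [0, 1], monotone in matched evidence.

    ``(matched fragments + 1 if the candidate's own diagnostic matched)
    / (predicted fragments + 1)``.  The returned value is before any
    contradiction demotion.
    """
    own_diag = any(m.label in DIAGNOSTIC_LABELS for m in result.matched)
    return (len(result.matched) + (1 if own_diag else 0)) / (
        result.n_predicted + 1
    )


def annotate(
    spectrum: Spectrum,
    candidates: Sequence[MCBACandidate],
    cfg: MatchConfig = MatchConfig(),
) -> List[AnnotationResult]:
    """Annotate a spectrum against candidates; best evidence first.

    For each candidate the predicted fragment set (in the spectrum's
    polarity) is matched greedily, then both diagnostic hypotheses from
    :func:`~mcba.fragments.diagnostic_pair` are tested regardless of the
    candidate's registry position.  A candidate whose registry amino
    position contradicts the spectrum's classification keeps its result
    but is demoted (score x 0.5) — the spectrum outranks the registry
    when deciding between isobaric candidates.

    Results are sorted by score (descending), then core abbreviation and
    acid name for determinism.
    """
    results: List[AnnotationResult] = []
    for cand in candidates:
        predicted = predict_fragments(cand, spectrum.polarity)
        matched = _greedy_assign(predicted, spectrum, cfg)
        alpha_mz, terminal_mz = diagnostic_pair(cand.acid)
        alpha_hit = _nearest_peak(spectrum, alpha_mz, cfg)
        terminal_hit = _nearest_peak(spectrum, terminal_mz, cfg)
        if alpha_hit and terminal_hit:
            dm = "both"
        elif alpha_hit:
            dm = "alpha"
        elif terminal_hit:
            dm = "terminal"
        else:
            dm = "none"
        result = AnnotationResult(
            spectrum_id=spectrum.identifier,
            candidate=cand,
            precursor_ppm=ppm_error(
                spectrum.precursor_mz, cand.mz(spectrum.polarity)
            ),
            matched=matched,
            n_predicted=len(predicted),
            diagnostic_matched=dm,
            classification="unclassified",
            score=0.0,
            confirmed=len(matched) >= cfg.min_fragments_for_id,
            alpha_intensity=alpha_hit[1] if alpha_hit else None,
            terminal_intensity=terminal_hit[1] if terminal_hit else None,
        )
        result.classification = classify_amino_position(result)
        result.score = score(result)
        if (
            result.classification in ("alpha", "terminal")
            and cand.acid.amino_position.value != result.classification
        ):
            result.score *= DEMOTION_FACTOR
            result.demoted = True
        results.append(result)
    results.sort(
        key=lambda r: (
            -r.score,
            r.candidate.core.abbreviation,
            r.candidate.acid.name,
        )
    )
    return results


def annotate_spectra(
    spectra: Sequence[Spectrum],
    library: Sequence[MCBACandidate],
    cfg: MatchConfig = MatchConfig(),
) -> Dict[str, List[AnnotationResult]]:
    """Match + annotate each spectrum against the library."""
    return {
        s.identifier: annotate(s, match_precursor(s, library, cfg), cfg)
        for s in spectra
    }


def top_annotations(
    results_by_spectrum: Dict[str, List[AnnotationResult]],
) -> Dict[str, Optional[AnnotationResult]]:
    """The best-scoring result per spectrum (None when nothing matched)."""
    return {
        sid: (results[0] if results else None)
        for sid, results in results_by_spectrum.items()
    }


def classification_census(
    results_by_spectrum: Dict[str, List[AnnotationResult]],
) -> Counter:
    """Count spectra by the classification of their top-scoring candidate.

    Spectra with no candidate at all count as ``unclassified``.
    """
    census: Counter = Counter()
    for top in top_annotations(results_by_spectrum).values():
        census[top.classification if top else "unclassified"] += 1
    return census
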