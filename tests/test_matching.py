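"""Precursor matching, greedy fragment annotation and classification."""

import numpy as np
import pytest

from mcba.chem import IonMode
from mcba.fragments import predict_positive
from mcba.matching import (
    MatchConfig,
    annotate,
    annotate_spectra,
    classification_census,
    match_precursor,
    top_annotations,
)
from mcba.spectra import Spectrum


def spectrum_for(identifier, table2, _cache={}):
    return next(s for s in table2 if s.identifier == identifier)


class TestMatchPrecursor:
    def test_isobaric_candidates_all_returned(self, library):
        s = Spectrum("q", 476.3735, IonMode.POSITIVE, [], [])
        hits = match_precursor(s, library)
        names = {(c.core.abbreviation, c.acid.name) for c in hits}
        assert names == {
            ("LCA", "valine"),
            ("LCA", "5-aminovaleric acid"),
            ("isoLCA", "valine"),
            ("isoLCA", "5-aminovaleric acid"),
        }

    def test_leucine_conjugate_precursor(self, library):
        s = Spectrum("q", 490.3906, IonMode.POSITIVE, [], [])
        hits = match_precursor(s, library)
        assert {c.acid.name for c in hits} == {"leucine"}
        assert len(hits) == 2  # LCA and isoLCA

    def test_unmatched_precursor_gives_empty_list(self, library):
        s = Spectrum("q", 200.0, IonMode.POSITIVE, [], [])
        assert match_precursor(s, library) == []

    def test_polarity_respected(self, library):
        s_neg = Spectrum("q", 488.3745, IonMode.NEGATIVE, [], [])
        neg_hits = match_precursor(s_neg, library)
        assert {c.acid.name for c in neg_hits} == {"leucine"}
        assert {c.core.abbreviation for c in neg_hits} == {"LCA", "isoLCA"}
        # in positive mode the same m/z can only pick up the near-isobaric
        # oxo-core leucine conjugates (C30H49NO4), never the C30H51NO4 ones
        s_pos = Spectrum("q", 488.3745, IonMode.POSITIVE, [], [])
        for cand in match_precursor(s_pos, library):
            assert str(cand.conjugate_formula) != "C30H51NO4"


class TestAnnotate:
    def test_leucine_fixture_row_matches_residue_series(
        self, library, table_fixtures
    ):
        _, table2 = table_fixtures
        s = spectrum_for("12", table2)
        results = annotate(s, match_precursor(s, library))
        top = results[0]
        assert top.candidate.acid.name == "leucine"
        observed = {round(m.observed_mz, 4) for m in top.matched}
        assert {132.1018, 86.0959} <= observed
        assert top.diagnostic_matched == "alpha"
        assert top.classification == "alpha"
        assert top.confirmed

    def test_aminovaleric_fixture_row_classified_terminal(
        self, library, table_fixtures
    ):
        _, table2 = table_fixtures
        s = spectrum_for("15", table2)
        results = annotate(s, match_precursor(s, library))
        top = results[0]
        assert top.candidate.acid.name == "5-aminovaleric acid"
        assert any(round(m.observed_mz, 4) == 100.0714 for m in top.matched)
        assert top.classification == "terminal"
        # the isobaric valine candidates contradict the spectrum: demoted
        valine = [r for r in results if r.candidate.acid.name == "valine"]
        assert valine and all(r.demoted for r in valine)
        assert all(r.score < top.score for r in valine)

    @pytest.mark.parametrize(
        "row, expected",
        [("21", "terminal"), ("20", "alpha"), ("19", "terminal"), ("22", "alpha")],
    )
    def test_aminobutyric_isomer_rows(self, library, table_fixtures, row, expected):
        _, table2 = table_fixtures
        s = spectrum_for(row, table2)
        top = annotate(s, match_precursor(s, library))[0]
        assert top.classification == expected

    def test_peakless_spectrum_unclassified(self, library):
        s = Spectrum("empty", 476.3735, IonMode.POSITIVE, [], [])
        for result in annotate(s, match_precursor(s, library)):
            assert result.matched == []
            assert result.diagnostic_matched == "none"
            assert result.classification == "unclassified"
            assert result.score == 0.0
            assert not result.confirmed

    def test_observed_peak_consumed_once_per_candidate(self, library):
        # one peak exactly between nothing: a single diagnostic-region peak
        # cannot be assigned to two predicted fragments
        cand = next(
            c for c in library
            if (c.core.abbreviation, c.acid.name) == ("LCA", "valine")
        )
        s = Spectrum("x", cand.mz_pos, IonMode.POSITIVE,
                     [118.08625], [1.0])
        (result,) = annotate(s, [cand])
        assert len(result.matched) == 1


class TestScore:
    def test_full_match_scores_one(self, library):
        cand = next(
            c for c in library
            if (c.core.abbreviation, c.acid.name) == ("LCA", "4-aminobutyric acid")
        )
        predicted = predict_positive(cand)
        s = Spectrum("full", cand.mz_pos, IonMode.POSITIVE,
                     [f.mz for f in predicted], np.ones(len(predicted)))
        (result,) = annotate(s, [cand])
        assert result.score == 1.0

    def test_partial_match_follows_formula(self, library):
        cand = next(
            c for c in library
            if (c.core.abbreviation, c.acid.name) == ("LCA", "4-aminobutyric acid")
        )
        predicted = predict_positive(cand)
        keep = [f.mz for f in predicted
                if f.label in ("backbone_2", "protonated_acid",
                               "diagnostic_terminal")]
        s = Spectrum("part", cand.mz_pos, IonMode.POSITIVE,
                     keep, np.ones(len(keep)))
        (result,) = annotate(s, [cand])
        # 3 matched incl. diagnostic out of 7 predicted -> (3+1)/(7+1)
        assert result.n_predicted == 7
        assert result.score == pytest.approx(4 / 8)


class TestInvariances:
    def test_census_of_fixture_spectra(self, library, table_fixtures):
        _, table2 = table_fixtures
        census = classification_census(annotate_spectra(table2, library))
        assert census["alpha"] == 9
        assert census["terminal"] == 4
        assert census.get("ambiguous", 0) == 0
        assert census.get("unclassified", 0) == 0

    def test_widening_tolerance_never_loses_matches(self, library, table_fixtures):
        _, table2 = table_fixtures
        counts = []
        for scale in (0.25, 0.5, 1.0, 2.0, 4.0):
            cfg = MatchConfig(
                frag_tol_low_da=0.02 * scale, frag_tol_ppm=10.0 * scale
            )
            total = 0
            for s in table2:
                for r in annotate(s, match_precursor(s, library, cfg), cfg):
                    total += len(r.matched)
            counts.append(total)
        assert counts == sorted(counts)

    def test_classification_invariant_to_permutation_and_scaling(
        self, library, table_fixtures
    ):
        _, table2 = table_fixtures
        s = spectrum_for("21", table2)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(s))
        permuted = Spectrum(
            s.identifier, s.precursor_mz, s.polarity,
            s.mz[order], s.intensity[order] * 1e4,
        )
        base = annotate(s, match_precursor(s, library))
        scaled = annotate(permuted, match_precursor(permuted, library))
        assert [r.classification for r in base] == [
            r.classification for r in scaled
        ]
        assert [r.score for r in base] == [r.score for r in scaled]


def test_top_annotations_and_census_handle_no_candidates(library):
    s = Spectrum("lonely", 200.0, IonMode.POSITIVE, [], [])
    results = annotate_spectra([s], library)
    assert top_annotations(results) == {"lonely": None}
    assert classification_census(results)["unclassified"] == 1
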