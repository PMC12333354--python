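"""Synthetic-spectrum generation, determinism and recovery evaluation."""

import numpy as np
import pytest

from mcba.building_blocks import AminoPosition
from mcba.chem import IonMode
from mcba.fragments import predict_fragments
from mcba.matching import annotate_spectra, top_annotations
from mcba.simulate import (
    SimulationConfig,
    TruthRecord,
    evaluate_recovery,
    simulate_dataset,
    simulate_spectrum,
)

NOISELESS = dict(
    precursor_ppm_sigma=0.0,
    frag_ppm_sigma=0.0,
    frag_mda_sigma=0.0,
    dropout_prob=0.0,
    n_noise_peaks=0,
)


@pytest.fixture()
def small_library(library):
    return [c for c in library if c.core.abbreviation in ("LCA", "isoLCA")]


def test_degenerate_model_reproduces_predicted_set(candidate_lookup):
    cand = candidate_lookup[("LCA", "valine")]
    cfg = SimulationConfig(**NOISELESS, seed=1)
    spectrum, truth = simulate_spectrum(cand, cfg, np.random.default_rng(1))
    predicted = sorted(f.mz for f in predict_fragments(cand, IonMode.POSITIVE))
    assert np.allclose(spectrum.mz, predicted)
    assert spectrum.precursor_mz == pytest.approx(cand.mz_pos)
    assert truth.acid == "valine" and truth.amino_position.value == "alpha"


def test_terminal_candidate_gets_terminal_diagnostic_only(candidate_lookup):
    cand = candidate_lookup[("LCA", "4-aminobutyric acid")]
    cfg = SimulationConfig(**NOISELESS, seed=1)
    spectrum, _ = simulate_spectrum(cand, cfg, np.random.default_rng(1))
    assert np.any(np.isclose(spectrum.mz, 86.06004, atol=1e-4))
    assert not np.any(np.isclose(spectrum.mz, 58.06513, atol=1e-4))


def test_same_seed_same_dataset(tmp_path, small_library):
    cfg = SimulationConfig(n_per_candidate=2, seed=42)
    paths = [(tmp_path / f"{i}.mgf", tmp_path / f"{i}.tsv") for i in (0, 1)]
    for mgf, tsv in paths:
        simulate_dataset(small_library, cfg, mgf, tsv)
    assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
    assert paths[0][1].read_bytes() == paths[1][1].read_bytes()


def test_different_seeds_differ_but_counts_match(small_library):
    cfg_a = SimulationConfig(n_per_candidate=3, seed=1)
    cfg_b = SimulationConfig(n_per_candidate=3, seed=2)
    spectra_a, truth_a = simulate_dataset(small_library, cfg_a)
    spectra_b, truth_b = simulate_dataset(small_library, cfg_b)
    assert len(spectra_a) == len(spectra_b) == 3 * len(small_library)
    assert len(truth_a) == len(truth_b) == len(spectra_a)
    assert not np.array_equal(spectra_a[0].mz, spectra_b[0].mz)


def test_noise_free_recovery_is_perfect(library):
    cfg = SimulationConfig(**NOISELESS, n_per_candidate=1, seed=5)
    spectra, truths = simulate_dataset(library, cfg)
    report = evaluate_recovery(annotate_spectra(spectra, library), truths)
    assert report.accuracy == 1.0
    assert report.n == len(library)


def test_recovery_degrades_monotonically_with_noise(small_library, library):
    accuracies = []
    for level in (
        dict(**NOISELESS),
        dict(),  # defaults: 2/3 ppm, 4 mDa, dropout 0.2, 5 noise peaks
        dict(precursor_ppm_sigma=8.0, frag_ppm_sigma=40.0,
             frag_mda_sigma=25.0, dropout_prob=0.8, n_noise_peaks=20),
    ):
        cfg = SimulationConfig(n_per_candidate=4, seed=77, **level)
        spectra, truths = simulate_dataset(small_library, cfg)
        report = evaluate_recovery(annotate_spectra(spectra, library), truths)
        accuracies.append(report.accuracy)
    assert accuracies[0] == 1.0
    assert accuracies[0] >= accuracies[1] >= accuracies[2]
    assert accuracies[2] < 1.0


def test_noise_alone_rarely_fakes_a_diagnostic(small_library, library):
    cfg = SimulationConfig(
        n_per_candidate=5, seed=9, force_diagnostic_dropout=True
    )
    spectra, _ = simulate_dataset(small_library, cfg)
    tops = top_annotations(annotate_spectra(spectra, library))
    false_calls = sum(
        1 for top in tops.values()
        if top and top.classification in ("alpha", "terminal")
    )
    assert false_calls / len(spectra) <= 0.05


class TestEvaluateRecovery:
    def test_perfect_predictions(self, small_library, library):
        cfg = SimulationConfig(**NOISELESS, seed=3)
        spectra, truths = simulate_dataset(small_library, cfg)
        report = evaluate_recovery(annotate_spectra(spectra, library), truths)
        assert report.accuracy == 1.0
        assert set(report.per_class) == {"alpha", "terminal", "other", "none"}
        assert report.confusion.to_numpy().sum() == len(spectra)

    def test_all_unclassified_scores_zero_for_diagnostic_classes(self):
        truths = [
            TruthRecord("a", "LCA", "valine", AminoPosition.ALPHA)
        ]
        report = evaluate_recovery({"a": []}, truths)
        assert report.accuracy == 0.0

    def test_id_mismatch_raises(self):
        truths = [
            TruthRecord("a", "LCA", "valine", AminoPosition.ALPHA)
        ]
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_recovery({"b": []}, truths)
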