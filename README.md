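# mcba

Discovery and structural-isomer classification of **microbially conjugated
bile acids (MCBAs)** from tandem mass spectra.

Gut bacteria re-conjugate bile acids with amino acids and related
nitrogenous acids, producing amides such as valolithocholic acid
(valine + lithocholic acid). Many of these conjugates are positional
isomers: valine and 5-aminovaleric acid, or 2-, 3- and 4-aminobutyric
acid, share one molecular formula, so their conjugates share one
precursor *m/z* and identical negative-mode fragmentation. This package
implements the MS/MS workflow that separates them:

1. **Candidate library** — every bile-acid core × nitrogenous-acid amide,
   with conjugate formula `core + acid − H₂O` and singly charged
   [M+H]⁺ / [M−H]⁻ *m/z* from IUPAC monoisotopic masses and the proton
   mass (1.00727646 Da).
2. **Fragment prediction** — per polarity: in negative mode the
   deprotonated acid residue (e.g. *m/z* 116.0717 for valine conjugates)
   and CO₂ loss; in positive mode the water-loss ladder of the steroid
   backbone (*m/z* 359.29/341.28/323.27 for lithocholate conjugates), the
   released protonated acid, and the **diagnostic neutral loss**:
   * amino group on the α carbon → loss of H₂O + CO (−46.0055 Da),
   * amino group at the chain terminus → loss of H₂O (−18.0106 Da).
   The two hypotheses are exactly one CO (27.9949 Da) apart.
3. **Matching & classification** — ppm precursor matching (isobaric
   candidates all retained), greedy nearest-peak fragment annotation under
   a two-regime tolerance (20 mDa below 150 Da, 10 ppm above), testing of
   both diagnostic hypotheses per candidate, and an evidence score in
   [0, 1]; candidates whose registry amino position contradicts the
   spectrum's diagnostic are demoted.
4. **Synthetic spectra** — a QTOF-like generator (Gaussian mass error in
   the same two regimes, fragment dropout, uniform noise peaks, log-normal
   intensities) with ground-truth labels for end-to-end validation.

It is aimed at metabolomics researchers annotating LC-MS/MS runs of fecal,
intestinal or culture samples, and ships editable CSV registries of
bile-acid cores and nitrogenous acids plus fixtures transcribing the
reference identification tables (10 bile acids, 13 MCBAs).

## Worked example

```bash
$ mcba reproduce-tables results/
census: alpha=9 terminal=4 total=13 (reports in results)
```

The 13 packaged MCBA fixture spectra, annotated against the default
104-candidate library, classify into 9 α-carbon conjugates (leucine,
valine, 2-aminobutyric) and 4 terminal-amino conjugates (5-aminovaleric,
4-aminobutyric/GABA) — with no ambiguous or unclassified spectra.

From Python:

```python
>>> from mcba import *
>>> from mcba.building_blocks import packaged_data_path
>>> library, groups = build_library(default_cores(), default_acids())
>>> spectra = read_mgf(packaged_data_path("table2.mgf"))
>>> s = next(x for x in spectra if x.identifier == "15")  # precursor 476.3751, 1+
>>> top = annotate(s, match_precursor(s, library))[0]
>>> top.candidate.name, top.classification, round(top.score, 3)
('5-aminovaleric acid-LCA', 'terminal', 0.75)
```

A precursor near *m/z* 476.37 matches four isobaric C₂₉H₄₉NO₄ candidates
(valine / 5-aminovaleric × LCA / isoLCA); the observed fragment at
*m/z* ~100.07 (protonated acid 118.086 − H₂O) identifies the terminal
isomer and demotes the valine candidates.

End-to-end self-check on synthetic data:

```bash
$ python analysis/03_simulate_recover.py --seed 1
noise-free: accuracy 1.000 over 112 spectra (alpha=1.00 none=1.00 other=1.00 terminal=1.00)
   default: accuracy 1.000 over 112 spectra (alpha=1.00 none=1.00 other=1.00 terminal=1.00)
     harsh: accuracy 0.580 over 112 spectra (alpha=0.45 none=1.00 other=1.00 terminal=0.43)
```

Under the default QTOF-like noise model the amino-group position of every
simulated conjugate is recovered; under deliberately harsh noise (25 mDa
low-mass error, 80 % dropout, 20 noise peaks) accuracy degrades, as it
should.

## Command line

`mcba build-library`, `mcba annotate`, `mcba reproduce-tables`,
`mcba simulate`, `mcba evaluate` — run `mcba --help` for options. The
numbered scripts under `analysis/` drive the same package code and write
their tables under `results/`.

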