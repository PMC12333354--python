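# Methods

## The identification problem

Microbially conjugated bile acids (MCBAs) are amides of a bile-acid core
(lithocholic acid and its epimers and oxo-derivatives, chenodeoxycholic
acid, etc.) with an amino acid or related nitrogenous acid, condensed at
the C24 acyl position. Because conjugation is combinatorial and many
nitrogenous acids are positional isomers of one another, an observed
precursor *m/z* rarely identifies a single compound: valine and
5-aminovaleric acid are both C₅H₁₁NO₂, and 2-, 3- and 4-aminobutyric acid
are all C₄H₉NO₂. Negative-mode MS/MS releases the deprotonated acid
residue, which confirms *that* a conjugate is present but is identical for
all positional isomers. The discriminating signal is in positive mode:
after the protonated acid is released from the conjugate it fragments a
second time, and the neutral it loses depends on the position of its
amino group.

## Mass model

All masses derive from one constants table: IUPAC monoisotopic atomic
masses for C, H, N, O, S to 8 decimals, and the proton mass
1.00727646 Da. Using the proton (rather than the hydrogen atom) mass
accounts for the electron and reproduces the reference ppm values to the
printed 2 decimals. Neutral-loss masses (H₂O, CO, CO₂) are derived from
the atomic table, never stored independently. Charge state is fixed at 1;
multiply charged ions are rejected at I/O. Only ±H ionisation is
modelled — no Na⁺/NH₄⁺ adducts and no isotope patterns.

## Candidate library

`conjugate_formula = core + acid − H₂O`, element-wise on formulas. Only
the C24-acyl amide is modelled: ester conjugates are excluded (retention
behaviour of synthesized ester standards rules them out as the observed
species), as are double conjugation, sulfation and glucuronidation.
A library over *n* cores and *m* acids contains exactly *n·m* candidates;
same-formula candidates are kept separate and grouped into isobaric
groups, because disambiguating them is the job of the positive-mode
diagnostics, not of the library. Stereochemistry is carried only in names
and the `epimer_of` field — epimers share formulas and MS cannot separate
them; retention times are stored as optional metadata, never predicted.

The packaged registries hold the thirteen bile-acid cores evidenced in
the reference tables (CDCA, LCA, isoLCA, UDCA, isoUDCA, isoCDCA, DCA, CA,
HDCA and four oxo-forms) and eight nitrogenous acids (glycine, valine,
leucine, 2-/3-/4-aminobutyric, 5-aminovaleric, taurine). Taurine carries
`amino_position = none`: its sulfonic-acid chemistry is outside the
−46/−18 rule, so taurine conjugates participate in precursor matching but
are never classified. Registries are user-editable CSVs; extending them
(e.g. to all proteinogenic amino acids) changes the library without
touching code.

## Fragment prediction

Negative mode, per candidate: [M−H]⁻, the deprotonated acid residue
(`mass(acid) − proton`), and [M−H−CO₂]⁻.

Positive mode: [M+H]⁺, [M+H−H₂O]⁺, the backbone water-loss ladder
`[core + H − k·H₂O]⁺` for k = 1..n_hydroxyl+2 (the amide cleavage itself
consumes one water equivalent, which is why a mono-hydroxyl core such as
lithocholic acid shows three effective losses: *m/z* 359.29, 341.28,
323.27), the protonated free acid, and exactly one diagnostic ion:

| amino position | diagnostic loss from protonated acid | example |
|---|---|---|
| α-carbon | H₂O + CO (−46.0055 Da) | valine: 118.086 → 72.081 |
| terminal | H₂O (−18.0106 Da) | GABA: 104.071 → 86.060 |
| other / none | none asserted | 3-aminobutyric acid, taurine |

Diagnostics are computed from the free acid, not the intact conjugate:
the acid is released first and fragments second. For any acid the two
hypothetical diagnostics are exactly one CO apart (27.9949 Da), so both
hypotheses can be tested on an unknown without risk of confusion. For
β-amino acids no rule is asserted — no fragmentation rule has been
demonstrated for them, and such candidates can only come out
unclassified. Relative intensities are not predicted; a fragment set is a
set.

## Matching and classification

Defaults (all user-configurable, `MatchConfig`):

* `precursor_tol_ppm = 10` — the reference records show up to |4.6| ppm
  observed error; 10 ppm gives headroom without admitting unrelated
  formulas (the nearest confusable near-isobars sit tens of mDa away).
* `frag_tol_low_da = 0.02` below 150 Da — printed low-mass diagnostic
  ions deviate from theory by up to ~10 mDa (e.g. 72.0704 observed vs
  72.0808 theoretical), a known QTOF behaviour for small immonium-type
  ions at high collision energy.
* `frag_tol_ppm = 10` at/above 150 Da — backbone ions agree to <1 mDa.
* `min_fragments_for_id = 2` — a precursor match alone never confirms a
  candidate.

Each predicted fragment is assigned to the nearest observed peak within
tolerance, globally smallest |Δ| first; an observed peak supports at most
one predicted fragment per candidate, so one peak cannot double-count as
two diagnostics. Both diagnostic hypotheses are then tested against the
spectrum. Classification: α if only the −46 diagnostic matched, terminal
if only the −18 matched, ambiguous if both (tie broken by matched-peak
intensity when intensities are informative; with uniform intensities the
tie stands), unclassified if neither.

Score = (matched fragments + 1 if the candidate's own diagnostic
matched) / (predicted fragments + 1) ∈ [0, 1], monotone in evidence.
Isobaric candidates are never collapsed; instead a candidate whose
registry amino position contradicts the spectrum's classification is
demoted (score × 0.5). This is what resolves, e.g., a 476.37 precursor
whose spectrum shows the 100.076 ion: the 5-aminovaleric candidate keeps
its score, the valine candidate is demoted. The demotion factor is a
ranking device, not a probability; any value in (0, 1) yields the same
ranking here because undemoted isobaric competitors match the same
backbone fragments.

## Synthetic data generator

The generator emulates the QTOF spectra this workflow targets, with
defaults chosen from the deviation pattern of the printed reference
values: precursor error σ = 2 ppm (printed |ppm| ≤ 4.6), fragment error
σ = 3 ppm at/above 150 Da and σ = 4 mDa below (printed low-mass
deviations up to ~10 mDa ≈ 2.5σ), fragment dropout probability 0.2 per
non-protected fragment (reference spectra list 2–5 of ~7 predicted
fragments), 5 uniform noise peaks over *m/z* 50–1100 (the acquisition
range plus low-mass headroom), and log-normal intensities
(meanlog 0, sdlog 1) since no reference intensities exist and
classification must be scale-invariant. The precursor peak and the
diagnostic ion are never dropped — at the collision energies used for
classification these are the anchoring ions; a separate
`force_diagnostic_dropout` switch removes the diagnostic everywhere and
serves as the negative control (noise peaks alone must not produce
α/terminal calls at a rate above 5 %).

What the generator does *not* emulate: chromatography (co-elution,
peak shapes, retention-time structure), isotope envelopes, correlated
calibration drift, intensity structure of real fragmentation, and
real-matrix interferences. Passing recovery tests therefore demonstrate
the correctness and noise-robustness of the matching logic, not
instrument-grade performance on real samples.

Determinism: a dataset is fully determined by (library, config, seed);
MGF and truth files are byte-identical across runs. The RNG is numpy's
default generator; only within-implementation determinism is promised.

## Evaluation

`evaluate_recovery` scores the top-ranked classification per spectrum
against the generating acid's amino position; for acids with position
`other`/`none` the correct call is `unclassified`. Reported problem
sizes: the fixture census runs the 13 reference spectra against the full
104-candidate library; recovery runs use the 16 lithocholic/
isolithocholic candidates × 7 replicates (112 spectra, ~50 per diagnostic
class) annotated against all 104 candidates — large enough for stable
rates while keeping the whole suite fast.

## Numerical and degenerate-input choices

* ppm is reported rounded to 2 decimals in outputs; full precision kept
  internally.
* Formula subtraction that would drive an element negative raises; an
  empty formula has mass 0.
* Peak lists are sorted ascending by *m/z* on construction; empty spectra
  are legal and yield empty matches, `unclassified`, score 0.
* Annotation output ordering is deterministic: score descending, then
  core abbreviation, then acid name.
* Reference-table ppm values for the MCBA (positive-mode) table are
  internally inconsistent across same-formula rows and are stored as
  transcription metadata only; recomputation is asserted only for the
  bile-acid (negative-mode) table.

## Known limitations

* Enantiomers (d/l) are indistinguishable by MS; the package does not
  attempt them.
* β-position acids cannot be positively classified, only left
  unclassified — no diagnostic rule exists for them.
* No collision-energy-dependent intensity model; candidate ranking under
  uniform intensities relies on fragment counts and the demotion rule.
* No retention-time prediction; RT fields are carried through for the
  user's own orthogonal checks.
* No false-discovery-rate machinery for large cohorts; the score ranks
  candidates within a spectrum, it is not calibrated across datasets.
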