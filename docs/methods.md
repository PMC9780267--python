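# Methods

## Mass arithmetic

Monoisotopic masses are hard-coded IUPAC values (≥ 6 decimals) for C, H, N,
O, P and S. Quasi-molecular ions are singly charged negative-mode species:

* `[M−H]⁻` : m/z = M − m(H) + m(e⁻) = M − 1.007276 Da
* `[M+HCOOH−H]⁻` : m/z = M + m(CH₂O₂) − 1.007276 Da

The proton-mass convention (subtract the hydrogen *atom*, add back the
electron) is deliberate: it reproduces reference calculated m/z values such
as 679.3699 for C36H56O12 at 4-decimal precision, which plain H-atom
subtraction does not. Mass error is the signed quantity
Δppm = (obs − calc)/calc × 10⁶. The packaged library records two m/z-error
rows whose printed sign is inconsistent with their own (calc, obs) pair;
these values are carried as data and excluded from arithmetic checks.

## Reference compound library

`saponet/data/compound_library.tsv` holds 40 characterized constituents of
the combined ginseng–polygala extract with formula, retention time
(35-min UHPLC gradient), calculated and observed quasi-molecular m/z,
fragment ions, class, and a reference-confirmation flag (12 records).
The loader is checksum-guarded and validates the 40/12 invariants. Two
records (19, 39) carry no fragment list and yield flagged zero-peak
spectra. No intensities were recorded, so library-derived spectra are
unit-intensity throughout and every downstream score is defined to behave
sensibly under flat intensities.

Three library rows are internally anomalous (one calculated m/z is
~1.1 mDa off the formate arithmetic for its formula; one is inconsistent
with its formula altogether). Annotation therefore gates precursors against
the *stored* calculated m/z — the value the library was actually assigned
under — falling back to formula-derived adduct m/z only when no stored
value exists. This choice is what makes the library self-consistent
(40/40 self-annotation).

## In-silico fragmentation (synthetic data)

A `StructureTemplate` is an aglycone plus an ordered stack of residues
drawn from: glucose residue (C6H10O5, 162.0528), rhamnose residue
(C6H10O4, 146.0579), pentose residue (C5H8O4, 132.0423), intact pentose
(C5H10O5, 150.0528), p-hydroxybenzoyl (C7H6O3), trimethoxycinnamoyl-type
(C12H16O5), and the small groups H2O, COOH and CH2OH. The last two are
modelled as the net even-electron losses CO2 (43.9898) and CH2O (30.0106):
this reproduces observed saponin ladders (517.32 → 499.31 → 455.32 →
425.31) where radical-mass bookkeeping would miss the ions by ~1 Da.

Fragments are generated by prefix-closed sequential cleavage along the
substituent order (terminal sugars first), matching the arrow-cascade
picture of glycoside CID; a `powerset` flag enables all-subsets generation
for users who prefer over-generation. Aromatic acyl residues additionally
emit their deprotonated anion (C7H5O3⁻ at 137.0244; C12H15O5⁻ at 239.0925),
the high-response signature of oligosaccharide esters. Every fragment
formula is element-wise contained in the template formula, and consecutive
ladder ions differ by exactly one residue mass.

Cohort generation uses one representative aglycone per class
(class abstractions, not structure elucidations):

| class | stripped core | fixed cascade tail | variable glucosyls |
|---|---|---|---|
| PPD | C30H52O3 | — | 2–6 |
| PPT | C30H52O4 | — | 2–6 |
| OLE | C30H48O3 | — | 2–6 |
| polygala-saponin | C28H42O3 | glc, H2O, CO2, CH2O | +0–4 |
| oligosaccharide-ester | C12H22O11 (sucrose) | trimethoxycinnamoyl, p-hydroxybenzoyl | +0–4 |
| xanthone | C16H10O6 | glc, pentose residue, H2O | +0–4 |

The saponin template with zero extra glucosyls reassembles C36H56O12
(tenuifolin); the xanthone tail terminates in the 315.05 → 297.04 pair.
Variable glucosyl counts sweep their range cyclically rather than i.i.d.
randomly so that every simulated class forms a *connected* homologous
series regardless of cohort size or seed; the seed drives m/z jitter
(Gaussian, default sd 0) and uniform noise peaks (default 0, drawn over
m/z 100–2000, the instrument scan range). Simulated spectra are
deterministic under a fixed seed and configuration.

What the generator does **not** emulate: fragment intensities (all peaks
are unit intensity), ring cleavages of the xanthone core (the 150.0528
internal loss is representable only as a residue loss), positional
isomerism of sugar attachment, co-eluting chimeric spectra, and instrument
mass-calibration bias. That last point matters for interpreting tests:
reference *observed* diagnostic ions run up to ~13 ppm above theoretical
ladder values at high m/z, so simulated (theoretical) ladders sit several
mDa below some rule ions. Passing tests demonstrate the pipeline's logic
under controlled conditions, not instrument-level performance on real data.

## Classification

Six packaged `ClassRule`s (editable TSV) carry the diagnostic ions per
class — PPD {783.4992, 621.4428}; PPT {799.4928, 637.4374, 475.3813};
OLE {793.4468, 475.3813, 455.3555}; polygala saponins {679.3759, 455.3189};
oligosaccharide esters {137.0248, 239.0566}; xanthones {297.0414,
315.0519} — and the characteristic losses {162.0528, 146.0579} for the
saponin/ginsenoside classes, {162.0528} for esters, and {132.0423,
150.0528, 162.0528} for xanthones.

* Ion matching: each peak is assigned to its nearest diagnostic ion within
  the ion tolerance (default 0.01 Da — observed ions deviate from rule
  masses by up to ~7 mDa); an ion counts once however many peaks support
  it.
* Loss matching: candidate differences are precursor→fragment plus all
  fragment→fragment pairs, matched to the nearest characteristic loss
  within the loss tolerance (default 0.02 Da, since observed losses
  deviate up to ~7 mDa from residue masses).
* Score: ion_weight (2) × ions + loss_weight (1) × losses. Diagnostic ions
  are class-specific, losses are shared — hence the asymmetric weights.
* Eligibility: ≥ 1 diagnostic ion **or** ≥ 2 characteristic losses; a
  single 162.0528 loss is common to four classes and is not evidence.
* Ties: higher score, then more matched ions, then the fixed specificity
  order PPT > OLE > PPD > polygala-saponin > ester > xanthone; residual
  ties are reported in the result.

No numeric match tolerance was recorded with the reference data; the
defaults above are this package's choices and are configurable everywhere.

`library_agreement` compares rule classification against the library's
class column for the 38 records with fragments. Agreement holds for every
record whose own class's diagnostic ions appear in its fragment list
(29 records); the remaining 9 are emitted as a disagreement report rather
than silently accepted — they comprise rows whose recorded fragment lists
lack their class's diagnostic ions (e.g. ester rows recording 137.054
where the p-hydroxybenzoyl anion is 137.0248) and one ginsenoside row
whose recorded class contradicts its own fragment ions.

## Molecular networking

The similarity score is the modified cosine: greedy one-to-one peak
matching in decreasing intensity-product order, a pair being admissible
when its m/z difference is within `frag_tol` (default 0.02 Da) either
directly or — with precursor-shift matching — offset by the precursor mass
difference. The score is Σ(intensity products)/(‖a‖·‖b‖) ∈ [0, 1]; under
flat intensities it is n_matched/√(n_a·n_b). Arguments are canonically
ordered internally, so the score is exactly symmetric. Greedy matching is
the documented algorithm; an exhaustive assignment oracle in the test
suite bounds its deviation from the optimal matching.

Network construction keeps edges with score ≥ 0.7 and ≥ 3 matched peaks,
then applies a mutual top-k filter (k = 10): an edge survives only if it
ranks within the k strongest of both endpoints. Clusters ("regions") are
connected components — the simplest construction consistent with six
visually separated class regions; community detection is out of scope.

**Design note — precursor shift off by default for region extraction.**
For pure homologous glycan ladders, shifted matching aligns the ladders of
*different* aglycone classes peak-for-peak at the constant precursor
offset (a PPD and an OLE ladder differ by 4.03 Da throughout and would
score 1.0), which collapses all saponin classes into one region. That
linking of analogs is precisely what the modified cosine is designed to
do, but it is the wrong default for class-region extraction, so
`build_network` defaults to `precursor_shift=False` while
`modified_cosine` itself keeps the standard shifted definition as its
default. Analog networking remains one flag away.

## Annotation

Candidates are gated by |Δppm| ≤ 10 against the stored calculated m/z (see
above), then by |ΔRT| ≤ 0.5 min when both retention times are present
(simulated spectra carry none, so RT gating is skipped for them), and
ranked by fragment corroboration (number of library fragments with a query
peak within 0.02 Da), then |Δppm|, then RT proximity, then record index.
Isobaric records (three library entries share a calculated m/z of
991.5472) are all returned, resolved by fragments and RT. Tiers:
`reference-confirmed` (flagged record), `database-match` (≥ 1
corroborating fragment), `class-only` (precursor/RT evidence alone). One
corroborating fragment as the database-match threshold is this package's
choice; no stricter criterion was recorded with the reference data.

## Problem sizes and determinism

Simulated cohorts in the tests use 5 spectra per class (30 total), the
cohort size at which every class range is fully swept; the networking and
recovery checks run in seconds. The end-to-end recovery conditions are:
noiseless (jitter 0, no noise) — 100% class recovery and six class-pure
network regions; degraded (jitter sd 0.005 Da, 5 noise peaks, seed 0) —
≥ 90% recovery. Every stochastic component flows from a single
`numpy.random.default_rng(seed)`; pipelines, cohorts and output files are
byte-identical under a fixed seed and configuration.

## Known limitations

* Classification of spectra that show only shared sugar losses (no
  diagnostic ion) is decided by the fixed specificity order and is
  reported as a tie — such spectra are genuinely ambiguous under this rule
  set.
* The 0.01 Da ion tolerance spans most, but not all, of the gap between
  theoretical ladder masses and the observed-calibrated rule ions at
  m/z ≥ 780; heavily jittered PPD spectra are the dominant recovery
  failure mode.
* The network reproduces class regions, not any particular published
  network topology; score thresholds are conventions, not fitted values.
* Positive-mode adducts, multiple charging, isotope patterns and intensity
  prediction are out of scope.
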