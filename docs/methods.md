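# Methods

`pcbscreen` implements a nontarget LC-HRMS suspect-screening workflow for
metabolites of lower-chlorinated biphenyls (the worked system is PCB 2,
3-chlorobiphenyl, metabolized by HepG2 hepatoma cells), together with the
semi-quantitative profiling and mass-balance reasoning used to interpret
the screen. This note documents the model, its assumptions, the tunable
parameters, and the design choices that were genuinely open.

## Mass arithmetic

All masses are monoisotopic, computed from a fixed six-element table
(C 12 exactly, H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207117,
Cl 34.96885268 Da). Only the deprotonated molecular anion [M−H]⁻ is
modeled, the species under which conjugated biphenyl metabolites are
observed in negative-mode electrospray. Two deliberate conventions:

- **No electron-mass correction.** The anion m/z is the neutral
  monoisotopic mass minus one H-atom mass. Adding the ~5.5×10⁻⁴ Da
  electron term would shift every value by roughly half a millidalton and
  would *not* reproduce the calculated masses conventionally reported in
  screening tables; at the 10-ppm matching window either convention works,
  but reported values are defined without it.
- **Chlorine-only isotope simulation.** The isotopologue check uses the
  binomial ³⁵Cl/³⁷Cl ladder (abundances 0.7576/0.2424, M+2 spacing
  1.99705 Da) and ignores ¹³C. The halogen M+2 signature is what
  distinguishes a chlorinated candidate from a dechlorinated one; for
  C₁₂–C₁₉ compositions the ¹³C M+1 peak is irrelevant to that question,
  and the closed-form binomial keeps the check exact and testable against
  enumeration.

Mass error is the dimensionless |measured − calculated|/calculated × 10⁶
(ppm), always non-negative.

## Candidate generation

Metabolite candidates are *formulas plus substitution bookkeeping*, not
structures. Ring positions are unmodeled — the underlying experiments
cannot resolve them either — so one candidate may collect several
positional isomers, which are separated downstream by retention time.

The state tracks free hydroxyl, sulfate, glucuronide, methoxy, and
cysteinyl counts, remaining chlorines, and a catechol flag (set once two
free hydroxyls coexist; conjugation consumes a hydroxyl but does not clear
the flag, since the adjacent-dioxygen motif persists). Rules are formula
deltas gated by declarative preconditions:

| rule | delta | precondition | default cap |
|---|---|---|---|
| hydroxylation | +O | — | 3 |
| sulfation | +SO₃ | ≥1 free OH | 1 |
| glucuronidation | +C₆H₈O₆ | ≥1 free OH | 1 |
| methylation (COMT) | +CH₂ | catechol | 1 |
| cysteine conjugation | +C₃H₅NO₂S | ≥1 free OH | 1 |
| reductive dechlorination | −Cl +H | ≥1 free OH, ≥1 Cl | 1 |
| oxidative dechlorination | −Cl +OH | ≥1 free OH, ≥1 Cl | 1 |

The dechlorination precondition abstracts the ortho OH/Cl relationship of
the proposed arene-oxide/reductive pathway to "has a free hydroxyl",
the strongest statement available without regiochemistry. The
hydroxylation cap of 3 and the default closure depth of 5 are the minimal
settings that reach every named class: the methoxy-hydroxy sulfate classes
carry three oxidation-derived oxygens and take five rule applications
(e.g. OH → OH → methylate → OH → sulfate). Quinone, hydroquinone, and
glutathione chemistry is excluded from the default rule set — those
intermediates are not observed as stable products in this system — but
callers can append rules freely.

The closure is breadth-first, deduplicated on (anion formula, class
label), and sorted by mass so output is deterministic regardless of rule
order. Candidates matching one of the 13 named class signatures (1.1–4.5;
4.x = dechlorinated skeleton) get that label; everything else is an
`intermediate` and still participates in matching.

## Screening

1. **Mass matching.** Every feature–candidate pair within the ppm window
   (default 10 ppm, the conventional EIC extraction width) is kept; ties
   are ranked by |ppm| then by fewer transformation steps (parsimony).
2. **Isotope verification.** The observed (M+2)/M intensity ratio must lie
   within a relative tolerance (default 30%) of the binomial expectation
   for the candidate's chlorine count; for chlorine-free candidates the
   M+2 peak must be absent or below 5% of M. A missing cluster yields
   "untested", which never blocks a hit; a contradiction rejects it and is
   logged. The 30% tolerance is our choice — published screens typically
   verify the pattern by inspection — and is loose enough for one-scan
   intensity noise while still separating 0-Cl (0.0), 1-Cl (0.32), and
   2-Cl (0.64) hypotheses.
3. **MS/MS annotation.** Fragments are explained by a neutral-loss library
   whose masses are computed from formulas: H₂O, CO, CH₃, Cl, HCl, SO₃,
   the glucuronyl residue C₆H₈O₆, the dehydroalanine loss C₃H₅NO₂
   diagnostic of cysteine S-conjugates, all unordered two-loss
   combinations, and the SO₃⁻ radical anion as a diagnostic fragment ion.
   Matching tolerance is 0.01 Da — tighter than the 2-decimal precision at
   which screening tables print fragments, treating printed values as
   rounded. The precursor must match the candidate within the ppm window
   or the pairing is rejected.
4. **Confidence.** Level 1 only for classes on an explicit user-declared
   standards list; level 2 for mass + non-contradictory isotope pattern +
   ≥1 annotated fragment; level 3 for mass + isotope evidence only.
5. **Background exclusion.** A class whose control-group (vehicle)
   intensity reaches 10% of the lowest exposed-group intensity is flagged
   background and excluded. Published screens state only presence/absence
   in controls; the 10% ratio is our quantitative rendering of it.
6. **Isomer resolution.** Within one (class, formula), hits are clustered
   by retention time; a gap of ≥0.05 min starts a new isomer. The gap is
   compared strictly and after rounding to 10⁻⁶ min, because retention
   times carry ~0.01-min precision and two real isomers sit exactly
   0.05 min apart — float subtraction must not eat the threshold.

## MRI profiling and the impurity budget

Raw intensities are normalized to the co-run internal standard
(raw/IS × 1000) and divided by a per-class relative ionization efficiency
(IE) to give molecular response-independent (MRI) intensities; class
profiles are MRI percentages of the total. IE values are *inputs* (a
two-column table); predicting them is out of scope. With no table, IE = 1
everywhere, and the output is labelled a normalized — not MRI — profile
with a loud warning. Dechlorinated (biphenyl-series) classes convention-
ally keep IE = 1, mirroring how such screens report them. Within a class,
isomer normalized intensities are summed first and the class IE is the
mean of the isomer IEs; the alternative (correct each isomer, then sum)
differs only when isomer IEs differ, and the summation-first order matches
how class totals are reported.

Profiles across conditions are compared by cosine similarity
(cos θ = p·q/‖p‖‖q‖ ∈ [0, 1] for non-negative profiles; defined as 0 when
a profile has zero norm).

The impurity calculator converts a dosing scenario (parent concentration ×
volume × parent MW × impurity mass fraction in ng/mg ÷ impurity MW) into
moles of impurity, and — under the worst-case assumption that the impurity
converts completely into a single metabolite — into the maximum mass of
that metabolite. For the worked chlorobiphenyl scenario the average MWs
188.65 (parent) and 154.21 g/mol (biphenyl impurity) are config values.

## Synthetic data

`generate_dataset` plants ground-truthed metabolites and emits a feature
table, MGF spectra, and a truth table, fully reproducible from one seed:
Gaussian mass error (default σ = 2 ppm, the scale of the observed errors,
1.1–3.7 ppm), retention-time jitter (σ = 0.02 min), log-normal intensity
scatter (CV = 0.2), chlorine isotope clusters with 5% multiplicative
noise, diagnostic MS/MS fragments rounded to 2 decimals plus uniform-
random noise fragments (fragment intensities are uninformative, uniform
10–100% of base, since reference tables print none), and decoy features
drawn uniformly in mass while excluded from ±25 ppm around every planted
or caller-specified mass. The exclusion zone makes recall and false-match
rates identifiable properties of the matcher; real matrices offer no such
guarantee, so passing these tests does not bound false-discovery rates on
real data. Coelution, in-source fragmentation, saturation, and correlated
drift are not simulated.

`study_table_fixture` deterministically reconstructs the observed screening
table of the HepG2 study — 20 metabolites in 13 classes over a 10 μM and
a 3.6 nM exposure group, five not-detected low-dose cells omitted — by
shifting each calculated anion m/z up by the reported ppm error and
building spectra from the printed fragment lists. Screening it end-to-end
reproduces the published counts, confidence levels, and mass errors.

## Numerical and degenerate-input conventions

- Formula parsing accepts Hill order with optional trailing charge
  markers; unknown elements and zero counts are errors, not warnings.
- Rule application onto an infeasible state (negative element count or
  failed precondition) raises, and the generator silently skips such
  branches.
- `class_profile` on all-zero intensities warns and returns an empty
  profile; empty record lists are errors.
- An empty feature list screens to an empty report; missing MS/MS is
  never an error.
- All simulation randomness flows through one `numpy` Generator seeded
  explicitly; identical seeds give byte-identical outputs.

## Problem sizes

The bundled statistical checks run 20 simulation replicates of 13 planted
metabolites × 2 groups with 30 decoys each against the ~70-candidate
closure of the default rule set — ample to estimate a ≥0.95 recall /
≤0.05 false-match contrast given that a 10-ppm window sits 5σ from a
2-ppm mass-error distribution (tail mass ≈ 6×10⁻⁷).

## Known limitations

- No structures, no regiochemistry, no retention-time prediction: two
  metabolites with one formula and one class are distinguishable only by
  retention time.
- One fragment library for all classes; class-specific fragmentation
  beyond neutral losses (e.g. ring cleavages) is not modeled, so some
  printed fragments legitimately stay unassigned (the 174.99 fragment of
  the hydroxylated parent class is matched only via a user-extended
  library; we do not guess its identity).
- Intensities are semi-quantitative even after IE correction; no
  calibration to absolute concentrations is attempted.
- The isotope check uses only M+2/M; M+4 is carried in the data model but
  not scored, which is adequate up to ~2 chlorines.
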