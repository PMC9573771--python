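# pcbscreen

Nontarget LC-HRMS suspect screening of (chloro)biphenyl metabolites.

Lower-chlorinated polychlorinated biphenyls (PCBs) are airborne
environmental pollutants that human cells transform into complex mixtures
of hydroxylated, sulfated, glucuronidated, methoxylated, cysteinyl — and,
notably, *dechlorinated* — metabolites. None of these have authentic
standards, so they are identified by suspect screening: generate candidate
formulas from biotransformation rules, match them to high-resolution MS1
features by accurate mass, verify the chlorine isotope signature, annotate
MS/MS spectra by diagnostic neutral losses, and grade each hit with a
tiered confidence level. `pcbscreen` implements that workflow end to end
for people analyzing centroided feature lists from negative-mode
LC-Orbitrap/QTof experiments, plus the two quantitative arguments that
make such screens interpretable:

- **MRI profiling** — internal-standard-normalized intensities divided by
  per-class ionization efficiencies (IE), expressed as percentages, so
  metabolite profiles can be compared across exposures with cosine
  similarity (cos θ = p·q/‖p‖‖q‖);
- **impurity mass balance** — the moles of a trace impurity in the dosing
  material (concentration × volume × MW_parent × fraction / MW_impurity),
  bounding how much metabolite the impurity could possibly explain.

The core conventions: anion m/z is the neutral monoisotopic mass minus one
H (no electron-mass term); mass error is |m − m_calc|/m_calc × 10⁶ ppm
with a 10-ppm matching window; the (M+2)/M intensity ratio must agree with
the binomial ³⁵Cl/³⁷Cl expectation (0.32 for one Cl); confidence level 2
requires an annotated MS/MS fragment, level 3 accurate mass and isotope
pattern only, level 1 an authentic standard. See `docs/methods.md` for the
full model.

## Worked example

Generate the bundled reconstruction of a HepG2 screening experiment
(two exposure groups, high 10 μM and low 3.6 nM) and screen it:

```sh
pcbscreen simulate --fixture --out-dir sim
pcbscreen screen --features sim/features.tsv --ms2 sim/spectra.mgf --out-dir screen
```

which prints

```
20 metabolites in 13 classes (5 dechlorinated); reports in screen
```

— twenty distinct metabolites (a class with several retention times counts
one metabolite per isomer) across thirteen classes, five of which are
dechlorinated biphenyl conjugates. `screen/metabolites.tsv` begins:

```
class  metabolite         rt_min  anion_formula  calc_mz    intensity_high  ppm_high  intensity_low  ppm_low  ms2_matches  confidence
1.1    OH-PCB 2           5.43    C12H8ClO       203.02637  50.0            2.9       2.0            3.5      -HCl         2
1.2    PCB 2 sulfate      4.22    C12H8ClO4S     282.98318  80.0            1.9       16.2           2.0      -SO3         2
1.3    PCB 2 glucuronide  3.68    C18H16ClO7     379.05846  3.2             1.6       0.05           1.1      -C6H8O6      2
```

Each row is one annotated metabolite: its class, the calculated [M−H]⁻
m/z, per-group intensity and mass error in ppm, the neutral losses that
explained its fragments (e.g. `-SO3`, loss of 79.95682 Da, diagnostic of a
sulfate conjugate), and the resulting confidence level. The
`screen/similarity.tsv` matrix gives cos θ = 0.947 between the high- and
low-exposure profiles. Finally, the impurity bound:

```sh
pcbscreen impurity --concentration 10e-6 --volume 3e-3 --fraction 775
```

```json
{"impurity_mol": 2.844246482069905e-11, "impurity_pmol": 28.44246482069905}
```

i.e. dosing 3 mL of 10 μM parent compound carrying 775 ng/mg of a
biphenyl impurity introduces only ≈28.4 pmol of biphenyl — far too little
to account for robustly detected biphenyl-series metabolites, which is the
argument that they arise by metabolic dechlorination instead.

Other subcommands: `pcbscreen generate-candidates` (rule-closure candidate
table), `pcbscreen profile` (MRI percentages + similarity from an
intensity table), `pcbscreen simulate` without `--fixture` (randomized
ground-truthed datasets with decoys for validation). Everything is also
available as a library (`pcbscreen.chem`, `.biotransform`, `.screening`,
`.profiles`, `.synthetic`, `.io`).

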