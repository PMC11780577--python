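# oznox

Annotation and quantification of lipid double-bond (C=C) regioisomers from
LC-MS/MS data acquired with ozone/nitrogen-oxide source chemistry
(OzNOxESI), for lipidomics researchers working with glycerophospholipids
(PC, PE, PG, PI, PS, PA, and the lyso forms LPC, LPE, LPG) and free fatty
acids.

## The problem and the method

Lipids identical in class and chain composition can differ only in where
their C=C sit along the fatty acyl chains (e.g. FA 18:1(*n*-9) vs
*n*-7, positions counted from the methyl terminus). Classical in-source
ozonolysis (OzESI) cleaves each C=C into an aldehyde whose mass encodes the
position, but those aldehydes appear at the MS1 level, where coeluting
lipids make their parentage ambiguous. With nitrogen, oxygen and ozone in a
heated ESI source, unsaturated lipids instead form nitrogen-oxide adducts of
their secondary ozonides — [M+NO₄−H]⁺ in positive mode, [M+N₂O₇]⁻ in
negative mode (whose HCD-MS2 is dominated by NO₃⁻ at *m/z* 61.99). The
positive adduct is an ensemble over all C=C with a *single* m/z; selecting
it for HCD-MS2 yields C=C-diagnostic product ions unambiguously tied to
their precursor.

This package implements the data-processing side of that workflow:

1. **Mass bookkeeping** — parse shorthand annotations
   (`PC 16:0/22:6(n-3,6,9,12,15,18)`, `FA 18:1(n-9)`, sum compositions like
   `PC 37:3`, deuterated `d5-…` standards) and compute exact masses. A
   cleavage at position *p* with *u* C=C on its methyl side changes the
   retained fragment by −CₚH₍₂ₚ₋₂ᵤ₎+O, which fully determines every
   diagnostic m/z.
2. **Theoretical products** — OzESI aldehyde/Criegee MS1 products, OzNOx
   precursor adducts, and class-specific MS2 diagnostic ions: a
   per-C=C ion *pair* for PC (aldehyde and −CHO radical companion), the
   pair with and without headgroup loss for PE, headgroup-lost pairs for
   PG/PI/PS/PA (which therefore converge on identical m/z for shared
   acyls), *triplets* for LPE (−H₂O) and FA (ammoniated/protonated/−H₂O).
   Scheduled PRM target lists with class-optimal collision energies.
3. **Regioisomer logic** — detect diagnostic (p, u) events in PRM scans
   within ppm tolerance; enumerate candidate position patterns by chaining
   (the k-th C=C on a chain must carry u = k−1, positions strictly
   increase, spacing ≥ 2); score candidates scan-by-scan
   (coverage × purity, intensity-weighted) into probabilities.
4. **Quantification** — partition lipid signal across isomers by unique
   diagnostic ions (or non-negative least squares for shared-ion systems)
   under the position-independent response assumption, with a 1% relative
   abundance floor; ¹³C Type I isotope correction; single-point
   internal-standard absolute quantification.
5. **Simulation** — a seeded synthetic-run generator (Gaussian LC peaks,
   10% OzNOx adduct yield, class fragmentation rules, ppm jitter, noise)
   providing ground truth for every stage, including the classic
   coelution confound: the *n*-15 aldehyde of LPC 22:4(*n*-6,9,12,15) is
   formula-identical to the *n*-11 aldehyde of LPC 18:1.

## Worked example

Simulate a 75/25 mixture of LPC 18:1(*n*-9) and (*n*-7), then annotate it:

```sh
$ oznox simulate lpc_18_1_75_25 -o demo --seed 7
2 species, 12 ledger peaks -> demo

$ printf 'annotation\tretention_time_min\nLPC 18:1\t1.0\n' > demo/ann.tsv
$ oznox annotate demo/lpc_18_1_75_25.mzML -a demo/ann.tsv -o demo/reports
LPC 18:1: confirmed

$ cat demo/reports/quantified_isomers.tsv
annotation  candidate_positions  relative_abundance_pct  basis       pruned
LPC 18:1    n-7                  25.0                    unique_ion  False
LPC 18:1    n-9                  75.0                    unique_ion  False
```

Both regioisomers share one precursor m/z; their diagnostic ions differ
(p7u0 vs p9u0 cleavage events), each unique to one isomer, so the 75/25
split is recovered exactly from the MS2 intensities. Mass arithmetic is
also available directly:

```sh
$ oznox masscalc "PC 16:0/22:6(n-3,6,9,12,15,18)"
PC 16:0/22:6(n-3,6,9,12,15,18)  formula C46H80NO8P  M 805.5622
OzNOx precursor (+)             882.5365
```

Other CLI commands: `oznox targets` (PRM inclusion lists from an annotation
table) and `oznox simulate <preset|scenario.json>` with presets `pc_22_6`,
`pe_pair`, `fa_16_1_seven_isomers`, `lpc_coelution`, `lpc_18_1_75_25`.

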