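# Methods

## Mass model

All masses are monoisotopic (C 12 exactly, H 1.0078250319, D 2.0141017780,
N 14.0030740052, O 15.9949146221, P 30.97376151 Da). Adduct m/z includes the
electron mass: m/z = (M + Δ − z·mₑ)/|z|.

Lipid compositions are assembled from neutral zero-acyl core formulas
(glycerophosphocholine C₈H₂₀NO₆P, -ethanolamine C₅H₁₄NO₆P, -glycerol
C₆H₁₅O₈P, -serine C₆H₁₄NO₈P, -inositol C₉H₁₉O₁₁P, phosphatidic acid core
C₃H₉O₆P, free fatty acid core H₂O), each esterified chain adding
C_cH₍₂c₋₂₋₂d₎O. These reproduce accepted published formulas (validated in
tests, e.g. PC 16:0/18:1 = C₄₂H₈₂NO₈P). Sum compositions use the class's
real ester count, so `PC 34:1` and `PC 16:0/18:1` have identical formulas.
Deuterium labels are assumed to sit on the backbone/headgroup (retained in
all carboxyl-side product ions), matching the design of commercial
deuterated standard mixes; this is configurable off.

## Ozonolysis and nitrogen-oxide adduct bookkeeping

The chemistry is modeled purely as mass arithmetic. Cleaving the C=C at
n-position p with u C=C methyl-side of it removes C_pH₍₂p₋₂u₎ and adds one
O to the retained species. Consequences used throughout:

- aldehyde m/z strictly *decreases* with p (a larger methyl-side fragment is
  lost) and increases with u (each retained C=C keeps two H);
- the Criegee ion is aldehyde + O (15.9949 Da);
- the −CHO radical companion is aldehyde − 29.0027 Da;
- diagnostic m/z depends only on (p, u) and the total composition, so two
  chains carrying the same (p, u) give mass-degenerate ions, and different
  species can collide (the n-15 aldehyde of LPC 22:4(n-6,9,12,15) is
  formula-identical to the n-11 aldehyde of LPC 18:1).

OzNOx adducts: positive [M+NO₄−H]⁺ (ammonium-adduct classes PG, PI, LPG and
FA add NH₃; configurable), negative [M+N₂O₇]⁻. The negative adduct is
written in the field both with and without an additional proton loss; both
specs are registered and the hydrogen-retaining form is the default.

Headgroup neutral losses (positive mode, from the protonated species):
PE 141.0191 (C₂H₈NO₄P), PG 172.0137 (C₃H₉O₆P), PS 185.0089 (C₃H₈NO₆P),
PI 260.0297 (C₆H₁₃O₉P), PA 97.9769 (H₃PO₄), LPG as PG; ammonium-adduct
classes additionally shed NH₃. These are the unique values under which
PE/PG/PI/PS/PA diagnostic ions converge to identical m/z for shared acyl
compositions regardless of base adduct, which the tests enforce to 1e−6 Da.

Class MS2 schemes per C=C: PC/LPC pair {aldehyde, −CHO}; PE the pair with
headgroup lost, duplicated with headgroup retained (4 ions); PG/PI/PS/PA/LPG
the headgroup-lost pair; LPE triplet {aldehyde, −H₂O, −CHO}; FA trio
{ammoniated aldehyde, protonated aldehyde, −H₂O}. Criegee ions are MS1-only.
Lyso-specific precursor-level losses (NO₃, H₂O) are treated as
non-diagnostic context and never used for position calling.

Collision energies (normalized, per class): FA 10, PC 15, LPC 15 (inherited
from PC — the one inferred value), PE 25, LPE 15, PG 25, PI 23, PS 23,
LPG 23, PA 29. Overridable via a JSON rules file.

## Position legality and candidate chaining

Legal n-positions: minimum 2, maximum carbons − 2, successive positions ≥ 2
apart (admits conjugated and non-methylene-interrupted patterns; all three
bounds configurable). A detected (p, u) ion pins one C=C and the count of
C=C below it, so the k-th C=C of a chain (ascending) must come from an
event with u = k − 1. Candidate enumeration chains events under these
constraints per chain, takes the cross product over chains, and merges
candidates with identical expected-ion multisets (swapped identical chains,
degenerate two-chain events) into one equivalence class with chain
attribution marked ambiguous. A brute-force oracle (generate every legal
pattern, keep those whose full event set was detected) verifies the
chaining enumeration over all chains up to 22 carbons and 3 C=C.

For sum compositions (chain split unknown, e.g. `PC 37:3`) the legal p
range assumes all C=C may sit on one acyl of up to total carbons − 12
(12 being the shortest acyl considered; configurable). No chain split is
claimed in that case, only positions.

## Detection and scoring

Peak matching is ppm-based (inclusive boundary), defaults 5 ppm at MS1 and
10 ppm at MS2 — chosen for ~30k-resolution data, exposed as flags. PRM
scans belong to a target when the precursor lies within the isolation
half-width and the RT inside the window. An event is *detected* when at
least 2 of its class's diagnostic roles match in at least 3 scans (both
configurable) — a guard against single-peak noise.

The probability score is this package's construction: per scan,
score = coverage × purity, with coverage the fraction of the candidate's
expected events seen in the scan and purity the fraction of detected
diagnostic intensity the candidate explains; candidate scores are
intensity-weighted means over scans, normalized to probabilities summing
to 1. It is scale-invariant, deterministic, and reduces to certainty for a
uniquely explaining candidate; it is validated by parameter-recovery
properties on simulated truth, not against any external tool's scores.
Candidates below probability 0.01 are dropped before quantification.
Replicate runs are merged by intensity-weighted averaging of scores. When
more than 500 candidates survive, the engine reports candidates and scores
without quantification (manual-curation territory).

## Quantification

Partitioning assumes diagnostic-ion response is independent of C=C
position. With unique ions per isomer, abundance ∝ mean intensity of each
isomer's unique events; otherwise non-negative least squares on the 0/1
event-by-isomer incidence matrix. Isomers below 1% relative abundance are
pruned once, the remainder renormalized once (no iterative re-pruning, so
the operation is deterministic and order-independent). Position-dependent
response decline exists in the real chemistry for polyunsaturated PC; the
simulator can impose a per-position decline factor to probe robustness,
but the quantification model deliberately keeps the independence
assumption.

Type I isotope correction divides AUC by (1 − 0.0107)^nC (carbons only;
²H/¹⁵N/¹⁸O neglected). Absolute quantification is single-point against a
class-matched internal standard: conc = AUC_analyte/AUC_IS × conc_IS.
Calibration-curve regression is out of scope.

## Simulator

Each species is a Gaussian LC peak (default σ 0.05 min) with MS1 peaks for
the survey adduct, the OzNOx adduct at 10% of the precursor (the yield a
tuned source achieves), and OzESI aldehyde (5%) / Criegee (half the
aldehyde) per cleavage; PRM MS2 scans carry the class diagnostic ions for
every species inside the isolation window. Intensities scale with amount ×
Gaussian profile × decline^(within-chain rank); noise is multiplicative
log-normal, m/z jitter Gaussian in ppm, baseline uniform random peaks. All
randomness flows from one integer seed (no time or locale dependence), and
a ledger maps every non-baseline peak to its (species, role, cleavage).
The positive-mode run shows FA species at their ammoniated m/z at MS1.

Not emulated: isotope envelopes, detector saturation, chromatographic
tailing, real ozonolysis kinetics, matrix effects. Passing recovery tests
therefore demonstrates the correctness of the inference logic under the
stated response model, not instrument-grade performance on biological
extracts.

Default problem sizes: presets span 2 minutes of RT at a 0.02 min cycle
(~150 MS1 scans, ~50 PRM scans per target); the noise-recovery checks use
ten seeded replicates. These sizes make every stage's behavior observable
while keeping the full suite fast.

## Degenerate and edge inputs

Saturated species: no adduct, no products, empty detection. Events whose
(p, u) repeat across chains are flagged mass-degenerate and de-duplicated
in product lists. Empty EICs are allowed (area 0, no apex). Profile-mode
mzML is rejected rather than silently centroided. All-candidate pruning
falls back to the best-scoring candidate at 100%. RT is minutes everywhere;
intervals half-open [start, end).

## Known limitations

- Ether/plasmalogen lipids, sphingolipids, glycerolipids and C=C
  stereochemistry are out of scope.
- Negative-mode OzNOx MS2 yields no position-diagnostic ions and is used
  only for the NO₃⁻ bookkeeping.
- The probability score and the sum-composition position-range rule are
  this package's own constructions, documented above.
- Quantification accuracy degrades where the position-independence
  assumption fails (polyunsaturated PC with strong response decline).
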