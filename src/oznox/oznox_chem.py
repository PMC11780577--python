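"""Theoretical ozonolysis and OzNOx product generation.

In an ozone/nitrogen/oxygen-fed heated ESI source, unsaturated lipids undergo
two fates that this module books as mass arithmetic:

* classical in-source ozonolysis (OzESI): each C=C can be cleaved, giving an
  aldehyde (carboxyl-side fragment, observed at the MS1 level) and a Criegee
  ion at aldehyde + O;
* OzNOx adduction: nitrogen dioxide generated in situ converts the lipid
  secondary ozonide into nitrogen-oxide adducts — [M+NO4-H]+ in positive mode
  and [M+N2O7]- in negative mode.  The positive adduct is an ensemble over all
  C=C with a single m/z; HCD-MS2 of it yields C=C-diagnostic product ions
  whose pattern is lipid-class specific.

Cleaving the C=C at n-position ``p`` with ``u`` double bonds methyl-side of it
removes C_p H_(2p-2u) and adds one O to the retained (carboxyl-side) species;
that delta fully determines every diagnostic m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .lipid_core import (
    ADDUCTS,
    AdductSpec,
    ElementCounts,
    LipidAnnotation,
    adduct_mz,
    composition,
    formula,
)

__all__ = [
    "CleavageEvent",
    "TheoreticalProduct",
    "ClassRule",
    "CLASS_RULES",
    "NCE_TABLE",
    "HEADGROUP_NEUTRAL_LOSS",
    "PRMTarget",
    "enumerate_cleavages",
    "legal_pu_events",
    "cleavage_delta",
    "aldehyde_composition",
    "ozesi_products",
    "oznox_precursor",
    "oznox_ms2_products",
    "ms2_product",
    "expected_roles",
    "nitrate_anion_mz",
    "build_prm_targets",
    "write_prm_targets",
    "load_class_rules",
]

CHO = formula("CHO")          # radical companion loss, 29.0027 Da
H2O = formula("H2O")
NH3 = formula("NH3")
OXYGEN = formula("O")


@dataclass(frozen=True)
class CleavageEvent:
    """One ozonolysis cleavage: C=C at n-position ``p`` on chain
    ``chain_index``, with ``u`` C=C at strictly lower n-# on the same chain
    (lost with the methyl-side fragment)."""

    chain_index: int
    p: int
    u: int
    mass_degenerate: bool = False

    @property
    def pu(self) -> tuple[int, int]:
        return (self.p, self.u)


@dataclass(frozen=True)
class TheoreticalProduct:
    """An expected ion: role, composition, m/z, polarity and MS level."""

    role: str
    formula: ElementCounts
    mz: float
    polarity: str           # "+" or "-"
    ms_level: int
    cleavage: CleavageEvent | None = None
    annotation: LipidAnnotation | None = None


# roles
OZESI_ALDEHYDE = "ozesi_aldehyde"
OZESI_CRIEGEE = "ozesi_criegee"
OZNOX_PRECURSOR = "oznox_precursor"
NEGATIVE_OZNOX_PRECURSOR = "negative_oznox_precursor"
MS2_ALDEHYDE = "ms2_aldehyde"
MS2_ALDEHYDE_MINUS_CHO = "ms2_aldehyde_minus_CHO"
MS2_ALDEHYDE_MINUS_H2O = "ms2_aldehyde_minus_H2O"
MS2_HG_RETAINED = "ms2_headgroup_retained"
MS2_HG_RETAINED_MINUS_CHO = "ms2_headgroup_retained_minus_CHO"
MS2_AMMONIATED_ALDEHYDE = "ms2_ammoniated_aldehyde"
MS2_NITRATE = "ms2_nitrate"

#: Positive-mode headgroup neutral losses (from the protonated species).
#: These are the unique values making PE/PG/PI/PS diagnostic ions converge
#: for shared acyl compositions.
HEADGROUP_NEUTRAL_LOSS: dict[str, ElementCounts] = {
    "PE": formula("C2H8NO4P"),    # 141.0191
    "PG": formula("C3H9O6P"),     # 172.0137
    "PS": formula("C3H8NO6P"),    # 185.0089
    "PI": formula("C6H13O9P"),    # 260.0297
    "PA": formula("H3PO4"),       # 97.9769
    "LPG": formula("C3H9O6P"),
}

#: Class-optimal HCD normalized collision energies.
NCE_TABLE: dict[str, float] = {
    "FA": 10, "PC": 15, "LPC": 15, "PE": 25, "LPE": 15,
    "PG": 25, "PI": 23, "PS": 23, "LPG": 23, "PA": 29,
}


@dataclass(frozen=True)
class ClassRule:
    """Per-class OzNOx behavior: base adduct, collision energy, MS2 scheme."""

    lipid_class: str
    base_adduct: AdductSpec
    nce: float
    ms2_roles: tuple[str, ...]
    headgroup_neutral_loss: ElementCounts | None = None
    emit_headgroup_retained_pairs: bool = False
    ammoniated_precursor: bool = False

    @property
    def roles_per_cleavage(self) -> int:
        n = len(self.ms2_roles)
        if self.emit_headgroup_retained_pairs:
            n += 2
        return n


def _default_rules() -> dict[str, ClassRule]:
    H = ADDUCTS["[M+H]+"]
    NH4 = ADDUCTS["[M+NH4]+"]
    pair = (MS2_ALDEHYDE, MS2_ALDEHYDE_MINUS_CHO)
    rules = {
        "PC": ClassRule("PC", H, NCE_TABLE["PC"], pair),
        "LPC": ClassRule("LPC", H, NCE_TABLE["LPC"], pair),
        "PE": ClassRule(
            "PE", H, NCE_TABLE["PE"], pair,
            headgroup_neutral_loss=HEADGROUP_NEUTRAL_LOSS["PE"],
            emit_headgroup_retained_pairs=True,
        ),
        "LPE": ClassRule(
            "LPE", H, NCE_TABLE["LPE"],
            (MS2_ALDEHYDE, MS2_ALDEHYDE_MINUS_H2O, MS2_ALDEHYDE_MINUS_CHO),
        ),
        "PG": ClassRule(
            "PG", NH4, NCE_TABLE["PG"], pair,
            headgroup_neutral_loss=HEADGROUP_NEUTRAL_LOSS["PG"],
            ammoniated_precursor=True,
        ),
        "PI": ClassRule(
            "PI", NH4, NCE_TABLE["PI"], pair,
            headgroup_neutral_loss=HEADGROUP_NEUTRAL_LOSS["PI"],
            ammoniated_precursor=True,
        ),
        "PS": ClassRule(
            "PS", H, NCE_TABLE["PS"], pair,
            headgroup_neutral_loss=HEADGROUP_NEUTRAL_LOSS["PS"],
        ),
        "PA": ClassRule(
            "PA", H, NCE_TABLE["PA"], pair,
            headgroup_neutral_loss=HEADGROUP_NEUTRAL_LOSS["PA"],
        ),
        "LPG": ClassRule(
            "LPG", NH4, NCE_TABLE["LPG"], pair,
            headgroup_neutral_loss=HEADGROUP_NEUTRAL_LOSS["LPG"],
            ammoniated_precursor=True,
        ),
        "FA": ClassRule(
            "FA", ADDUCTS["[M-H]-"], NCE_TABLE["FA"],
            (MS2_AMMONIATED_ALDEHYDE, MS2_ALDEHYDE, MS2_ALDEHYDE_MINUS_H2O),
            ammoniated_precursor=True,
        ),
    }
    return rules


CLASS_RULES: dict[str, ClassRule] = _default_rules()


def load_class_rules(path: str | Path) -> dict[str, ClassRule]:
    """Override built-in class rules from a JSON config.

    The file maps class names to objects with any of the keys ``nce``,
    ``base_adduct`` (an adduct name), ``ammoniated_precursor``,
    ``emit_headgroup_retained_pairs``.
    """
    import json

    with open(path) as fh:
        cfg = json.load(fh)
    rules = dict(CLASS_RULES)
    for cls, over in cfg.items():
        if cls not in rules:
            raise ValueError(f"unknown lipid class {cls!r} in {path}")
        rule = rules[cls]
        kw = {}
        if "nce" in over:
            kw["nce"] = float(over["nce"])
        if "base_adduct" in over:
            kw["base_adduct"] = ADDUCTS[over["base_adduct"]]
        for key in ("ammoniated_precursor", "emit_headgroup_retained_pairs"):
            if key in over:
                kw[key] = bool(over[key])
        rules[cls] = replace(rule, **kw)
    return rules


# ---------------------------------------------------------------------------
# Cleavage enumeration and mass deltas
# ---------------------------------------------------------------------------

def enumerate_cleavages(annotation: LipidAnnotation) -> list[CleavageEvent]:
    """One cleavage event per C=C per chain.

    Requires complete n-positions.  ``u`` is the count of C=C at lower n-# on
    the same chain.  Events sharing (p, u) across chains produce identical
    product m/z and are flagged mass-degenerate.
    """
    if not annotation.positions_complete:
        raise ValueError(
            f"{annotation}: n-positions incomplete; cannot enumerate cleavages"
        )
    events: list[CleavageEvent] = []
    for ci, chain in enumerate(annotation.chains):
        for u, p in enumerate(sorted(chain.n_positions)):
            events.append(CleavageEvent(ci, p, u))
    seen: dict[tuple[int, int], int] = {}
    for ev in events:
        seen[ev.pu] = seen.get(ev.pu, 0) + 1
    return [
        replace(ev, mass_degenerate=seen[ev.pu] > 1) for ev in events
    ]


def legal_pu_events(
    annotation: LipidAnnotation,
    min_n: int = 2,
    min_spacing: int = 2,
    min_partner_chain: int = 12,
) -> list[tuple[int, int]]:
    """All (p, u) pairs any regioisomer of ``annotation`` could produce.

    For a chain with c carbons and d double bonds, a cleavage at (p, u) is
    legal when u C=C fit below p and d-1-u above it at the required spacing.
    For sum compositions (chain split unknown) the bound assumes all C=C may
    sit on one acyl of up to total_carbons - ``min_partner_chain`` carbons.
    """
    out: set[tuple[int, int]] = set()
    if annotation.sum_composition_only:
        chain_specs = [
            (annotation.total_carbons - min_partner_chain,
             annotation.total_double_bonds)
        ]
    else:
        chain_specs = [(c.carbons, c.double_bonds) for c in annotation.chains]
    for carbons, d in chain_specs:
        for u in range(d):
            lo = min_n + min_spacing * u
            hi = (carbons - 2) - min_spacing * (d - 1 - u)
            for p in range(lo, hi + 1):
                out.add((p, u))
    return sorted(out)


def cleavage_delta(event: CleavageEvent) -> Mapping[str, int]:
    """Signed element delta of the carboxyl-side cleavage product:
    -C_p H_(2p-2u) + O relative to the intact species."""
    return {"C": -event.p, "H": -(2 * event.p - 2 * event.u), "O": 1}


def aldehyde_composition(
    annotation: LipidAnnotation, event: CleavageEvent
) -> ElementCounts:
    """Neutral composition of the ozonolysis aldehyde for one cleavage.

    Deuterium labels sit on the backbone/headgroup and are retained in the
    carboxyl-side product.
    """
    return composition(annotation).apply_delta(cleavage_delta(event))


def _pu_aldehyde(annotation: LipidAnnotation, p: int, u: int) -> ElementCounts:
    return composition(annotation).apply_delta(
        {"C": -p, "H": -(2 * p - 2 * u), "O": 1}
    )


# ---------------------------------------------------------------------------
# Product generation
# ---------------------------------------------------------------------------

def ozesi_products(
    annotation: LipidAnnotation,
    rule: ClassRule | None = None,
    include_criegee: bool = True,
    dedupe_tol: float = 1e-6,
) -> list[TheoreticalProduct]:
    """Classical OzESI MS1 products: per-cleavage aldehyde (+ Criegee).

    Products are ionized with the class base adduct and de-duplicated by m/z
    within ``dedupe_tol`` Da (exact-formula collisions from mass-degenerate
    cleavages).
    """
    rule = rule or CLASS_RULES[annotation.lipid_class]
    adduct = rule.base_adduct
    polarity = "+" if adduct.charge > 0 else "-"
    out: list[TheoreticalProduct] = []
    for ev in enumerate_cleavages(annotation):
        ald = aldehyde_composition(annotation, ev)
        species = [(OZESI_ALDEHYDE, ald)]
        if include_criegee:
            species.append((OZESI_CRIEGEE, ald + OXYGEN))
        for role, neutral in species:
            mz = adduct_mz(neutral, adduct)
            if any(
                abs(p.mz - mz) <= dedupe_tol and p.role == role for p in out
            ):
                continue
            out.append(TheoreticalProduct(
                role, adduct.ion_composition(neutral), mz, polarity, 1,
                cleavage=ev, annotation=annotation,
            ))
    return out


def oznox_precursor(
    annotation: LipidAnnotation,
    polarity: str = "+",
    rule: ClassRule | None = None,
) -> TheoreticalProduct:
    """The OzNOx adduct of a lipid: a single m/z regardless of C=C count.

    Positive mode: [M+NO4-H]+ (with NH3 for ammonium-adduct classes).
    Negative mode: [M+N2O7]-.  Saturated lipids form no adduct.
    """
    if annotation.total_double_bonds < 1:
        raise ValueError(f"{annotation} is saturated; no OzNOx adduct forms")
    rule = rule or CLASS_RULES[annotation.lipid_class]
    if polarity == "+":
        name = "[M+NO4-H+NH3]+" if rule.ammoniated_precursor else "[M+NO4-H]+"
        role = OZNOX_PRECURSOR
    elif polarity == "-":
        name = "[M+N2O7]-"
        role = NEGATIVE_OZNOX_PRECURSOR
    else:
        raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
    adduct = ADDUCTS[name]
    neutral = composition(annotation)
    return TheoreticalProduct(
        role, adduct.ion_composition(neutral), adduct_mz(neutral, adduct),
        polarity, 1, annotation=annotation,
    )


def oznox_ms2_products(
    annotation: LipidAnnotation,
    rule: ClassRule | None = None,
) -> list[TheoreticalProduct]:
    """Positive-mode OzNOx HCD-MS2 diagnostic ions, one set per cleavage.

    Class schemes (per C=C):

    * PC/LPC — pair: aldehyde ion and its -CHO radical companion;
    * PE — the pair with headgroup lost, duplicated with headgroup retained;
    * PG/PI/PS/PA/LPG — headgroup-lost pair (ammonium-adduct classes also
      shed NH3, so all converge with PE for shared acyls);
    * LPE — triplet: aldehyde, -H2O, -CHO;
    * FA — trio: ammoniated aldehyde, protonated aldehyde, -H2O.
    """
    rule = rule or CLASS_RULES[annotation.lipid_class]
    out: list[TheoreticalProduct] = []
    for ev in enumerate_cleavages(annotation):
        for role in expected_roles(rule):
            out.append(ms2_product(annotation, rule, role, ev.p, ev.u, ev))
    return out


def expected_roles(rule: ClassRule) -> tuple[str, ...]:
    roles = tuple(rule.ms2_roles)
    if rule.emit_headgroup_retained_pairs:
        roles = roles + (MS2_HG_RETAINED, MS2_HG_RETAINED_MINUS_CHO)
    return roles


def ms2_product(
    annotation: LipidAnnotation,
    rule: ClassRule,
    role: str,
    p: int,
    u: int,
    cleavage: CleavageEvent | None = None,
) -> TheoreticalProduct:
    """One positive-mode MS2 diagnostic ion for cleavage position (p, u)."""
    from .lipid_core import ELECTRON_MASS

    ald = _pu_aldehyde(annotation, p, u)
    if role == MS2_AMMONIATED_ALDEHYDE:
        ion = ADDUCTS["[M+NH4]+"].ion_composition(ald)
    elif role in (MS2_HG_RETAINED, MS2_HG_RETAINED_MINUS_CHO):
        ion = ADDUCTS["[M+H]+"].ion_composition(ald)
        if role == MS2_HG_RETAINED_MINUS_CHO:
            ion = ion - CHO
    else:
        base = rule.base_adduct
        if base.charge < 0:
            # FA analyzes its OzNOx adduct in positive mode
            base = ADDUCTS["[M+H]+"]
        ion = base.ion_composition(ald)
        if base.name == "[M+NH4]+":
            ion = ion - NH3
        if rule.headgroup_neutral_loss is not None:
            ion = ion - rule.headgroup_neutral_loss
        if role == MS2_ALDEHYDE_MINUS_CHO:
            ion = ion - CHO
        elif role == MS2_ALDEHYDE_MINUS_H2O:
            ion = ion - H2O
        elif role != MS2_ALDEHYDE:
            raise ValueError(f"unknown MS2 role {role!r}")
    mz = ion.mass - ELECTRON_MASS
    return TheoreticalProduct(
        role, ion, mz, "+", 2, cleavage=cleavage, annotation=annotation
    )


def nitrate_anion_mz() -> float:
    """m/z of the NO3- product ion that dominates negative-mode OzNOx MS2."""
    return adduct_mz(formula("HNO3"), ADDUCTS["[M-H]-"])


# ---------------------------------------------------------------------------
# PRM target lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRMTarget:
    """A scheduled MS2 acquisition target."""

    precursor_mz: float
    rt_start: float
    rt_end: float
    nce: float
    polarity: str
    annotation: LipidAnnotation

    def __post_init__(self):
        if not self.rt_start < self.rt_end:
            raise ValueError("rt_start must precede rt_end")


def build_prm_targets(
    annotations: Iterable[LipidAnnotation],
    rt_window_min: float = 1.0,
    rules: Mapping[str, ClassRule] | None = None,
) -> list[PRMTarget]:
    """One positive-mode PRM target per unsaturated annotation, sorted by RT."""
    rules = rules or CLASS_RULES
    targets = []
    for ann in annotations:
        if ann.retention_time is None:
            raise ValueError(f"{ann}: retention time required for PRM target")
        if ann.total_double_bonds < 1:
            raise ValueError(f"{ann}: saturated species has no OzNOx target")
        rule = rules[ann.lipid_class]
        prec = oznox_precursor(ann, "+", rule)
        targets.append(PRMTarget(
            prec.mz,
            ann.retention_time - rt_window_min,
            ann.retention_time + rt_window_min,
            rule.nce, "+", ann,
        ))
    return sorted(targets, key=lambda t: (t.rt_start, t.precursor_mz))


def write_prm_targets(targets: Sequence[PRMTarget], path: str | Path) -> None:
    """Write a PRM target list as TSV (instrument inclusion-list shape)."""
    df = pd.DataFrame({
        "mz": [round(t.precursor_mz, 5) for t in targets],
        "polarity": [t.polarity for t in targets],
        "rt_start_min": [round(t.rt_start, 3) for t in targets],
        "rt_end_min": [round(t.rt_end, 3) for t in targets],
        "nce": [t.nce for t in targets],
        "annotation": [str(t.annotation) for t in targets],
    })
    df.to_csv(path, sep="\t", index=False)
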