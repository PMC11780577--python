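"""Lipid shorthand parsing and exact-mass arithmetic.

Supports the glycerophospholipid classes PC, PE, PG, PI, PS, PA, their lyso
forms LPC, LPE, LPG, and free fatty acids (FA), written in shorthand such as
``PC 16:0/22:6(n-3,6,9,12,15,18)``, ``FA 18:1(n-9)`` or the sum composition
``PC 37:3``.  Double-bond positions use n-# nomenclature: carbons counted from
the methyl (omega) terminus, so n-9 denotes the C=C between carbons 9 and 10
from the methyl end.

Masses are monoisotopic.  Adduct m/z values include the electron-mass
correction: m/z = (M + delta - z * m_e) / |z|.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementCounts",
    "formula",
    "AcylChain",
    "LipidAnnotation",
    "AdductSpec",
    "ADDUCTS",
    "CLASS_CORES",
    "LIPID_CLASSES",
    "PositionRules",
    "parse_annotation",
    "format_annotation",
    "composition",
    "acyl_composition",
    "monoisotopic_mass",
    "adduct_mz",
    "read_annotation_table",
]

#: Monoisotopic masses, Da.  D is deuterium (2H).
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "D": 2.0141017780,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

ELECTRON_MASS = 0.00054857990946
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS  # 1.007276...


class ElementCounts(Mapping[str, int]):
    """Immutable elemental composition (non-negative counts).

    Supports element-wise ``+`` and ``-``; subtraction below zero raises
    ``ValueError``.  Signed deltas (adduct gains/losses) are plain dicts and
    are applied with :meth:`apply_delta`.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if el not in ELEMENT_MASSES:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        self._counts = {el: n for el, n in sorted(merged.items()) if n != 0}

    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementCounts(out)

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(
                    f"subtraction drives {el} negative ({self} - {other})"
                )
        return ElementCounts(out)

    def apply_delta(self, delta: Mapping[str, int]) -> "ElementCounts":
        """Apply a signed per-element delta; raises if any count goes negative."""
        out = dict(self._counts)
        for el, n in delta.items():
            out[el] = out.get(el, 0) + n
            if out[el] < 0:
                raise ValueError(f"delta drives {el} negative")
        return ElementCounts(out)

    def substitute_deuterium(self, n: int) -> "ElementCounts":
        """Replace ``n`` hydrogens with deuterium."""
        if n == 0:
            return self
        return (self - ElementCounts(H=n)) + ElementCounts(D=n)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(ELEMENT_MASSES[el] * n for el, n in self._counts.items())

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementCounts):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        hill = ""
        for el in ("C", "H", "D", "N", "O", "P"):
            n = self[el]
            if n:
                hill += el + (str(n) if n != 1 else "")
        return hill or "(empty)"


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula(text: str) -> ElementCounts:
    """Parse a Hill-style formula string like ``'C9H16O3'``."""
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r}")
    return ElementCounts(counts)


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Monoisotopic mass of an elemental composition, Da."""
    return counts.mass


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: signed element delta and charge."""

    name: str
    delta: Mapping[str, int]
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    @property
    def delta_mass(self) -> float:
        return sum(ELEMENT_MASSES[el] * n for el, n in self.delta.items())

    def mz(self, neutral: ElementCounts) -> float:
        return adduct_mz(neutral, self)

    def ion_composition(self, neutral: ElementCounts) -> ElementCounts:
        """Elemental composition of the ion (electrons not counted)."""
        return neutral.apply_delta(self.delta)


def adduct_mz(neutral: ElementCounts, adduct: AdductSpec) -> float:
    """m/z of ``neutral`` under ``adduct``, with electron-mass correction."""
    ion_mass = neutral.apply_delta(adduct.delta).mass
    return (ion_mass - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)


ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in [
        AdductSpec("[M+H]+", {"H": 1}, +1),
        AdductSpec("[M+NH4]+", {"N": 1, "H": 4}, +1),
        AdductSpec("[M-H]-", {"H": -1}, -1),
        # OzNOx adducts: nitrogen-oxide adducts of the lipid secondary ozonide.
        AdductSpec("[M+NO4-H]+", {"N": 1, "O": 4, "H": -1}, +1),
        AdductSpec("[M+NO4-H+NH3]+", {"N": 2, "O": 4, "H": 2}, +1),
        AdductSpec("[M+N2O7]-", {"N": 2, "O": 7}, -1),
        AdductSpec("[M+N2O7-H]-", {"N": 2, "O": 7, "H": -1}, -1),
    ]
}


# ---------------------------------------------------------------------------
# Lipid classes and annotations
# ---------------------------------------------------------------------------

#: Neutral zero-acyl backbone+headgroup core formulas.  Acylation adds
#: C_c H_(2c-2-2d) O per chain (esterification accounted for).
CLASS_CORES: dict[str, ElementCounts] = {
    "PC": formula("C8H20NO6P"),
    "PE": formula("C5H14NO6P"),
    "PG": formula("C6H15O8P"),
    "PS": formula("C6H14NO8P"),
    "PI": formula("C9H19O11P"),
    "PA": formula("C3H9O6P"),
    "FA": formula("H2O"),
}
CLASS_CORES["LPC"] = CLASS_CORES["PC"]
CLASS_CORES["LPE"] = CLASS_CORES["PE"]
CLASS_CORES["LPG"] = CLASS_CORES["PG"]

#: Number of acyl chains per class.
CLASS_N_CHAINS: dict[str, int] = {
    "PC": 2, "PE": 2, "PG": 2, "PI": 2, "PS": 2, "PA": 2,
    "LPC": 1, "LPE": 1, "LPG": 1, "FA": 1,
}

LIPID_CLASSES = tuple(CLASS_N_CHAINS)


@dataclass(frozen=True)
class PositionRules:
    """Legality bounds for C=C n-positions on an acyl chain.

    min_n = 2 and spacing >= 2 admit conjugated and non-methylene-interrupted
    patterns while excluding chemically impossible placements; the maximum,
    carbons - 2, keeps a terminal CH3-CH= out.
    """

    min_n: int = 2
    max_n_offset: int = 2   # max position = carbons - max_n_offset
    min_spacing: int = 2

    def max_n(self, carbons: int) -> int:
        return carbons - self.max_n_offset

    def valid_pattern(self, carbons: int, positions: Iterable[int]) -> bool:
        pos = list(positions)
        if any(p < self.min_n or p > self.max_n(carbons) for p in pos):
            return False
        return all(b - a >= self.min_spacing for a, b in zip(pos, pos[1:]))


DEFAULT_POSITION_RULES = PositionRules()


@dataclass(frozen=True)
class AcylChain:
    """A fatty acyl chain: carbon count, double bonds, known n-positions."""

    carbons: int
    double_bonds: int
    n_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError("acyl chain needs >= 2 carbons")
        if not 0 <= self.double_bonds <= (self.carbons - 2) // 2:
            raise ValueError(
                f"{self.double_bonds} double bonds impossible on "
                f"{self.carbons} carbons"
            )
        object.__setattr__(self, "n_positions", tuple(self.n_positions))
        if self.n_positions:
            if len(self.n_positions) != self.double_bonds:
                raise ValueError(
                    f"position list {self.n_positions} inconsistent with "
                    f"{self.double_bonds} double bonds"
                )
            if not DEFAULT_POSITION_RULES.valid_pattern(
                self.carbons, self.n_positions
            ):
                raise ValueError(
                    f"illegal n-positions {self.n_positions} for "
                    f"{self.carbons}-carbon chain"
                )

    @property
    def positions_complete(self) -> bool:
        return len(self.n_positions) == self.double_bonds

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.n_positions:
            s += "(n-" + ",".join(str(p) for p in self.n_positions) + ")"
        return s


@dataclass(frozen=True)
class LipidAnnotation:
    """A parsed lipid species annotation."""

    lipid_class: str
    chains: tuple[AcylChain, ...]
    sum_composition_only: bool = False
    chain_linkage_resolved: bool = True
    deuterium_count: int = 0
    retention_time: float | None = None  # minutes

    def __post_init__(self):
        if self.lipid_class not in CLASS_N_CHAINS:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        object.__setattr__(self, "chains", tuple(self.chains))
        expected = 1 if self.sum_composition_only else CLASS_N_CHAINS[self.lipid_class]
        if len(self.chains) != expected:
            raise ValueError(
                f"{self.lipid_class} requires {expected} chain(s), "
                f"got {len(self.chains)}"
            )
        if self.deuterium_count < 0:
            raise ValueError("deuterium count must be >= 0")

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)

    @property
    def positions_complete(self) -> bool:
        return not self.sum_composition_only and all(
            c.positions_complete for c in self.chains
        )

    def with_rt(self, rt: float | None) -> "LipidAnnotation":
        return replace(self, retention_time=rt)

    def __str__(self) -> str:
        return format_annotation(self)


def acyl_composition(chain: AcylChain) -> ElementCounts:
    """Composition added by esterifying one acyl chain: C_c H_(2c-2-2d) O."""
    return ElementCounts(
        C=chain.carbons,
        H=2 * chain.carbons - 2 - 2 * chain.double_bonds,
        O=1,
    )


def composition(annotation: LipidAnnotation) -> ElementCounts:
    """Neutral elemental composition of an annotated lipid.

    Sum compositions are accepted: the chain split does not affect the total
    formula.  Deuterium labels substitute D for H.
    """
    total = CLASS_CORES[annotation.lipid_class]
    if annotation.sum_composition_only:
        # the class's real ester count still applies: n chains contribute
        # C_tot H_(2*C_tot - 2n - 2d) O_n in total
        n = CLASS_N_CHAINS[annotation.lipid_class]
        c = annotation.total_carbons
        d = annotation.total_double_bonds
        total = total + ElementCounts(C=c, H=2 * c - 2 * n - 2 * d, O=n)
    else:
        for chain in annotation.chains:
            total = total + acyl_composition(chain)
    return total.substitute_deuterium(annotation.deuterium_count)


# ---------------------------------------------------------------------------
# Shorthand parsing
# ---------------------------------------------------------------------------

_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:\(n-([\d,]+)\))?$")
_LABEL_RE = re.compile(r"^d(\d+)-", re.IGNORECASE)


def _parse_chain(token: str) -> AcylChain:
    m = _CHAIN_RE.match(token.strip())
    if not m:
        raise ValueError(f"chain token {token!r} does not match C:D pattern")
    carbons, dbs = int(m.group(1)), int(m.group(2))
    positions: tuple[int, ...] = ()
    if m.group(3):
        positions = tuple(int(p) for p in m.group(3).split(","))
        if list(positions) != sorted(set(positions)):
            raise ValueError(
                f"n-positions {positions} must be strictly increasing"
            )
    return AcylChain(carbons, dbs, positions)


def _split_chains(text: str) -> tuple[list[str], bool]:
    """Split on "/" or "_" outside parentheses; returns (tokens, sn_resolved)."""
    tokens, buf, depth, resolved = [], [], 0, True
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch in "/_" and depth == 0:
            tokens.append("".join(buf))
            buf = []
            if ch == "_":
                resolved = False
            continue
        buf.append(ch)
    tokens.append("".join(buf))
    return tokens, resolved


def parse_annotation(text: str) -> LipidAnnotation:
    """Parse a lipid shorthand annotation.

    Examples: ``"PC 16:0/22:6(n-3,6,9,12,15,18)"``, ``"FA 18:1(n-9)"``,
    ``"d5-PC 17:0/22:4(n-6,9,12,15)"``, ``"PE 16:1_18:1"``, ``"PC 37:3"``.
    """
    if not text or not text.strip():
        raise ValueError("empty annotation")
    work = text.strip()
    deuterium = 0
    m = _LABEL_RE.match(work)
    if m:
        deuterium = int(m.group(1))
        work = work[m.end():]
    parts = work.split(None, 1)
    if len(parts) != 2:
        raise ValueError(f"malformed annotation {text!r}")
    cls, chain_text = parts[0], parts[1].strip()
    if cls not in CLASS_N_CHAINS:
        raise ValueError(f"unknown lipid class token {cls!r} in {text!r}")
    tokens, resolved = _split_chains(chain_text)
    if any(not t.strip() for t in tokens):
        raise ValueError(f"malformed annotation {text!r}")
    chains = [_parse_chain(t) for t in tokens]
    n_expected = CLASS_N_CHAINS[cls]
    if len(chains) == n_expected:
        return LipidAnnotation(
            cls, tuple(chains),
            chain_linkage_resolved=(resolved or n_expected == 1),
            deuterium_count=deuterium,
        )
    if len(chains) == 1 and n_expected > 1:
        # sum composition, e.g. "PC 37:3"
        if chains[0].n_positions:
            raise ValueError(
                f"sum composition {text!r} cannot carry chain-level n-positions"
            )
        return LipidAnnotation(
            cls, (chains[0],), sum_composition_only=True,
            chain_linkage_resolved=False, deuterium_count=deuterium,
        )
    raise ValueError(
        f"{cls} takes {n_expected} chain(s); {text!r} has {len(chains)}"
    )


def format_annotation(annotation: LipidAnnotation) -> str:
    """Inverse of :func:`parse_annotation` (round-trips)."""
    sep = "/" if annotation.chain_linkage_resolved else "_"
    body = sep.join(str(c) for c in annotation.chains)
    label = f"d{annotation.deuterium_count}-" if annotation.deuterium_count else ""
    return f"{label}{annotation.lipid_class} {body}"


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV/CSV.

    Columns: ``annotation`` (required), ``retention_time_min`` and ``adduct``
    (optional).  Returns the table with a parsed ``parsed`` column of
    :class:`LipidAnnotation` objects (retention times attached).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if "annotation" not in df.columns:
        raise ValueError(f"{path}: missing required column 'annotation'")
    parsed = []
    for i, row in df.iterrows():
        try:
            ann = parse_annotation(str(row["annotation"]))
        except ValueError as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
        rt = row.get("retention_time_min")
        if rt is not None and pd.notna(rt):
            ann = ann.with_rt(float(rt))
        parsed.append(ann)
    df = df.copy()
    df["parsed"] = parsed
    return df
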