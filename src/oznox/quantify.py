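"""Partition lipid signal across confirmed regioisomers; relative and
absolute quantification.

Partitioning assumes the diagnostic-ion response is independent of C=C
position (each expected event of an isomer yields, on average, the same
signal per unit of that isomer).  When every surviving isomer owns at least
one *unique* diagnostic event — one no other surviving isomer expects — the
split is proportional to the mean intensity of each isomer's unique events.
Shared-ion systems fall back to non-negative least squares on the
event-by-isomer incidence matrix.  Isomers projected below a 1% relative
abundance floor are pruned once and the rest renormalized once.

Absolute concentrations use single-point internal-standard response factors
after Type I carbon-13 isotope correction of peak areas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .lipid_core import ElementCounts, LipidAnnotation
from .regioisomer_engine import DetectedEvent, RegioCandidate

__all__ = [
    "IsomerAbundance",
    "QuantResult",
    "partition_abundances",
    "isotope_correct_type1",
    "absolute_quant",
    "per_isomer_concentrations",
    "report",
    "C13_ABUNDANCE",
]

#: Natural carbon-13 isotopic abundance used for Type I correction.
C13_ABUNDANCE = 0.0107

RELATIVE_ABUNDANCE_FLOOR_PCT = 1.0


@dataclass
class IsomerAbundance:
    candidate: RegioCandidate
    relative_abundance: float      # percent of the lipid total, 0-100
    basis: str                     # unique_ion | least_squares | single_candidate
    pruned: bool = False


@dataclass
class QuantResult:
    annotation: LipidAnnotation
    auc: float
    corrected_auc: float
    concentration: float | None            # amount/volume units of the IS
    abundances: list[IsomerAbundance]

    @property
    def isomer_concentrations(self) -> list[tuple[IsomerAbundance, float]]:
        if self.concentration is None:
            return []
        return [
            (ab, self.concentration * ab.relative_abundance / 100.0)
            for ab in self.abundances
            if not ab.pruned
        ]


def partition_abundances(
    candidates: Sequence[RegioCandidate],
    detected: Sequence[DetectedEvent],
    floor_pct: float = RELATIVE_ABUNDANCE_FLOOR_PCT,
) -> list[IsomerAbundance]:
    """Split 100% of the lipid's diagnostic signal across candidates.

    Pruning below ``floor_pct`` is applied once, then abundances are
    renormalized once (no iterative re-pruning), keeping the operation
    deterministic and order-independent.
    """
    if not candidates:
        raise ValueError("no surviving candidates to partition")
    if len(candidates) == 1:
        return [IsomerAbundance(candidates[0], 100.0, "single_candidate")]
    by_pu = {ev.pu: ev for ev in detected}
    expect_count: dict[tuple[int, int], int] = {}
    for c in candidates:
        for pu in c.expected_event_set:
            expect_count[pu] = expect_count.get(pu, 0) + 1
    unique_events = [
        sorted(pu for pu in c.expected_event_set if expect_count[pu] == 1)
        for c in candidates
    ]
    if all(unique_events):
        basis = "unique_ion"
        raw = np.array([
            np.mean([by_pu[pu].total_intensity if pu in by_pu else 0.0
                     for pu in uniq])
            for uniq in unique_events
        ])
    else:
        basis = "least_squares"
        events = sorted(by_pu)
        a = np.array([
            [1.0 if pu in c.expected_event_set else 0.0 for c in candidates]
            for pu in events
        ])
        b = np.array([by_pu[pu].total_intensity for pu in events])
        raw, _ = nnls(a, b)
    total = raw.sum()
    if total <= 0:
        # degenerate: no signal attributable; best-scoring candidate at 100%
        best = max(candidates, key=lambda c: c.score)
        return [
            IsomerAbundance(c, 100.0 if c is best else 0.0,
                            basis, pruned=c is not best)
            for c in candidates
        ]
    pct = raw / total * 100.0
    pruned = pct < floor_pct
    if pruned.all():
        pruned = ~(pct == pct.max())
    kept_total = pct[~pruned].sum()
    out = []
    for c, p, pr in zip(candidates, pct, pruned):
        rel = 0.0 if pr else p / kept_total * 100.0
        out.append(IsomerAbundance(c, rel, basis, pruned=bool(pr)))
    return out


def isotope_correct_type1(auc: float, formula: ElementCounts) -> float:
    """Type I carbon-13 correction of a monoisotopic peak area.

    Scales the area by the fraction of the isotopologue distribution that the
    monoisotopic peak carries: corrected = auc / (1 - 0.0107)^nC.  2H, 15N and
    18O contributions are neglected.
    """
    if auc < 0:
        raise ValueError("auc must be >= 0")
    n_c = formula["C"]
    return auc / (1.0 - C13_ABUNDANCE) ** n_c


def absolute_quant(
    analyte_corrected_auc: float,
    is_corrected_auc: float,
    is_concentration: float,
) -> float:
    """Single-point internal-standard quantification.

    concentration = analyte AUC / IS AUC x IS concentration, using
    isotope-corrected AUCs and a class-matched (typically deuterated)
    internal standard.
    """
    if is_corrected_auc <= 0:
        raise ValueError("internal standard AUC must be positive")
    if is_concentration <= 0:
        raise ValueError("internal standard concentration must be positive")
    return analyte_corrected_auc / is_corrected_auc * is_concentration


def per_isomer_concentrations(result: QuantResult) -> dict[str, float]:
    """Isomer label -> absolute concentration; sums to the lipid total."""
    return {
        ab.candidate.label(): conc
        for ab, conc in result.isomer_concentrations
    }


def read_internal_standard_map(path: str | Path) -> pd.DataFrame:
    """Internal-standard map TSV: columns [annotation_pattern, is_annotation,
    is_concentration, units]."""
    df = pd.read_csv(path, sep="\t")
    required = {"annotation_pattern", "is_annotation", "is_concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_REPORT_TABLES = {
    "ms1_products": ["annotation", "role", "cleavage", "mz", "polarity"],
    "ms2_products": ["annotation", "role", "cleavage", "mz", "polarity"],
    "candidates": ["annotation", "candidate_positions", "score",
                   "probability", "unique_events", "n_scans_support"],
    "quantified_isomers": ["annotation", "candidate_positions",
                           "relative_abundance_pct", "basis", "pruned",
                           "concentration"],
}


def report(
    out_dir: str | Path,
    ms1_products: pd.DataFrame | None = None,
    ms2_products: pd.DataFrame | None = None,
    candidates: pd.DataFrame | None = None,
    quantified: pd.DataFrame | None = None,
    summary: Mapping | None = None,
) -> dict[str, Path]:
    """Write the four report TSVs plus a JSON run summary.

    Tables: theoretical/detected MS1 ozonolysis products, MS2 diagnostic
    products, regioisomer candidates with scores, and quantified isomers.
    Missing tables are emitted headers-only; row order is deterministic
    (annotation, then candidate positions / m/z).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {
        "ms1_products": ms1_products,
        "ms2_products": ms2_products,
        "candidates": candidates,
        "quantified_isomers": quantified,
    }
    paths: dict[str, Path] = {}
    for name, df in frames.items():
        cols = _REPORT_TABLES[name]
        if df is None or df.empty:
            df = pd.DataFrame(columns=cols)
        else:
            df = df.reindex(columns=cols)
            sort_cols = [c for c in ("annotation", "candidate_positions", "mz")
                         if c in df.columns]
            df = df.sort_values(sort_cols, kind="stable")
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    spath = out_dir / "summary.json"
    with open(spath, "w") as fh:
        json.dump(dict(summary or {}), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = spath
    return paths
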