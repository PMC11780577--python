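"""C=C regioisomer detection, enumeration and probability scoring.

Every cleavage of a C=C at n-position ``p`` with ``u`` double bonds on its
methyl side produces class-specific diagnostic ions whose m/z depends only on
(p, u) and the lipid's total composition.  A detected (p, u) ion therefore
pins one C=C *and* the count of C=C below it on the same chain — the chaining
constraint that prunes the combinatorial space of position patterns: on a
chain the k-th C=C (sorted ascending) must have u = k - 1, positions strictly
increase, and successive positions are at least two carbons apart.

Scoring is scan-by-scan: score(R, s) = coverage(R, s) * purity(R, s), where
coverage is the fraction of R's expected events detected in scan s and purity
the fraction of detected diagnostic intensity in s that R explains.  Candidate
scores are intensity-weighted means over scans; probabilities normalize the
scores to sum to one.  The formula is scale-invariant and reduces to
certainty for a uniquely explaining candidate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lipid_core import LipidAnnotation, PositionRules
from .oznox_chem import (
    CLASS_RULES,
    ClassRule,
    expected_roles,
    legal_pu_events,
    ms2_product,
)
from .spectra_io import DEFAULT_MS2_TOL_PPM, Scan, match_peak

__all__ = [
    "DetectedEvent",
    "RegioCandidate",
    "EngineConfig",
    "detect_events",
    "enumerate_candidates",
    "brute_force_candidates",
    "score_candidates",
    "align_replicates",
    "candidate_report",
]


@dataclass(frozen=True)
class EngineConfig:
    """Detection and scoring thresholds."""

    tol_ppm: float = DEFAULT_MS2_TOL_PPM
    min_roles: int = 2          # roles that must match for a detected event
    min_scans: int = 3          # scans an event must appear in
    probability_floor: float = 0.01
    candidate_cap: int = 500
    min_n: int = 2
    min_spacing: int = 2


DEFAULT_CONFIG = EngineConfig()


@dataclass
class DetectedEvent:
    """A (p, u) cleavage confirmed in PRM MS2 scans.

    ``per_scan`` maps scan index -> summed matched diagnostic intensity;
    ``per_role`` maps role name -> total matched intensity.
    """

    p: int
    u: int
    per_scan: dict[int, float] = field(default_factory=dict)
    per_role: dict[str, float] = field(default_factory=dict)

    @property
    def pu(self) -> tuple[int, int]:
        return (self.p, self.u)

    @property
    def n_scans(self) -> int:
        return len(self.per_scan)

    @property
    def total_intensity(self) -> float:
        return float(sum(self.per_scan.values()))


@dataclass
class RegioCandidate:
    """A complete per-chain n-position assignment."""

    positions: tuple[tuple[int, ...], ...]   # per chain, sorted ascending
    chain_ambiguous: bool = False
    score: float = 0.0
    probability: float = 0.0

    @property
    def expected_events(self) -> tuple[tuple[int, int], ...]:
        """Sorted multiset of (p, u) events this isomer would produce."""
        out = []
        for chain in self.positions:
            for u, p in enumerate(chain):
                out.append((p, u))
        return tuple(sorted(out))

    @property
    def expected_event_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.expected_events)

    def label(self) -> str:
        return "/".join(
            "n-" + ",".join(str(p) for p in chain) if chain else "sat"
            for chain in self.positions
        )


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_events(
    annotation: LipidAnnotation,
    prm_scans: Sequence[Scan],
    rule: ClassRule | None = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[DetectedEvent]:
    """Search PRM MS2 scans for diagnostic ions of every legal (p, u).

    An event is detected when at least ``config.min_roles`` of the class's
    diagnostic roles match in at least ``config.min_scans`` scans.  When the
    annotation carries complete n-positions the search still spans all legal
    (p, u) pairs (the annotation's positions are a hypothesis, not a filter).
    """
    if not prm_scans:
        raise ValueError("no PRM scans supplied")
    rule = rule or CLASS_RULES[annotation.lipid_class]
    roles = expected_roles(rule)
    events: list[DetectedEvent] = []
    for p, u in legal_pu_events(
        annotation, min_n=config.min_n, min_spacing=config.min_spacing
    ):
        targets = {
            role: ms2_product(annotation, rule, role, p, u).mz
            for role in roles
        }
        per_scan: dict[int, float] = {}
        per_role: dict[str, float] = {}
        scan_role_hits: dict[int, int] = {}
        for si, scan in enumerate(prm_scans):
            hit_roles = 0
            total = 0.0
            for role, mz in targets.items():
                peak = match_peak(scan, mz, config.tol_ppm)
                if peak is not None:
                    hit_roles += 1
                    total += peak.intensity
                    per_role[role] = per_role.get(role, 0.0) + peak.intensity
            if hit_roles >= config.min_roles:
                per_scan[si] = total
                scan_role_hits[si] = hit_roles
        if len(per_scan) >= config.min_scans:
            events.append(DetectedEvent(p, u, per_scan, per_role))
    return events


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _chain_patterns(
    carbons: int,
    double_bonds: int,
    detected_pu: frozenset[tuple[int, int]],
    config: EngineConfig,
) -> list[tuple[int, ...]]:
    """All position patterns for one chain fully supported by detected events.

    Built by chaining: the k-th C=C must come from a detected event with
    u = k - 1, lie above the previous position by >= min_spacing, and leave
    room for the remaining C=C below carbons - 2.
    """
    if double_bonds == 0:
        return [()]
    max_p = carbons - 2
    by_u: dict[int, list[int]] = {}
    for p, u in detected_pu:
        if config.min_n <= p <= max_p:
            by_u.setdefault(u, []).append(p)
    results: list[tuple[int, ...]] = []

    def extend(prefix: tuple[int, ...]) -> None:
        k = len(prefix)
        if k == double_bonds:
            results.append(prefix)
            return
        remaining = double_bonds - 1 - k
        for p in sorted(by_u.get(k, [])):
            if prefix and p - prefix[-1] < config.min_spacing:
                continue
            if p > max_p - config.min_spacing * remaining:
                continue
            extend(prefix + (p,))

    extend(())
    return results


def enumerate_candidates(
    annotation: LipidAnnotation,
    detected: Sequence[DetectedEvent],
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[RegioCandidate]:
    """All regioisomers whose full expected-event set was detected.

    Chains receive exactly their double-bond count of events; candidates with
    identical expected-event multisets (e.g. swapped identical chains, or
    two chains carrying the same (p, u)) are merged into one equivalence
    class with chain attribution marked ambiguous.
    """
    if not detected:
        return []
    pu = frozenset(ev.pu for ev in detected)
    if annotation.sum_composition_only:
        chain_specs = [
            (annotation.total_carbons - 12, annotation.total_double_bonds)
        ]
    else:
        chain_specs = [(c.carbons, c.double_bonds) for c in annotation.chains]
    per_chain = [
        _chain_patterns(carbons, d, pu, config) for carbons, d in chain_specs
    ]
    merged: dict[tuple, RegioCandidate] = {}
    for combo in itertools.product(*per_chain):
        cand = RegioCandidate(tuple(combo))
        key = cand.expected_events
        if key in merged:
            if merged[key].positions != cand.positions:
                merged[key].chain_ambiguous = True
        else:
            merged[key] = cand
    return sorted(merged.values(), key=lambda c: c.positions)


def brute_force_candidates(
    annotation: LipidAnnotation,
    detected: Sequence[DetectedEvent],
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[RegioCandidate]:
    """Independent oracle: generate every legal position pattern outright and
    keep those whose full expected-event set is within the detected set.

    Exponential in chain length; intended for small chains in tests.
    """
    pu = frozenset(ev.pu for ev in detected)
    rules = PositionRules(min_n=config.min_n, min_spacing=config.min_spacing)
    chain_specs = [(c.carbons, c.double_bonds) for c in annotation.chains]
    per_chain: list[list[tuple[int, ...]]] = []
    for carbons, d in chain_specs:
        pats = [
            pat
            for pat in itertools.combinations(range(2, carbons - 1), d)
            if rules.valid_pattern(carbons, pat)
            and all((p, u) in pu for u, p in enumerate(pat))
        ]
        per_chain.append(pats)
    merged: dict[tuple, RegioCandidate] = {}
    for combo in itertools.product(*per_chain):
        cand = RegioCandidate(tuple(combo))
        key = cand.expected_events
        if key in merged:
            if merged[key].positions != cand.positions:
                merged[key].chain_ambiguous = True
        else:
            merged[key] = cand
    return sorted(merged.values(), key=lambda c: c.positions)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_candidates(
    candidates: Sequence[RegioCandidate],
    detected: Sequence[DetectedEvent],
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[RegioCandidate]:
    """Scan-by-scan probability scoring.

    Per scan: coverage x purity (see module docstring); candidate score is
    the mean over scans weighted by each scan's total detected diagnostic
    intensity.  Probabilities normalize scores over candidates; candidates
    below ``config.probability_floor`` are dropped and the rest renormalized
    (once).  Deterministic; invariant under uniform intensity scaling.
    """
    if not candidates:
        return []
    by_pu: dict[tuple[int, int], DetectedEvent] = {ev.pu: ev for ev in detected}
    scan_ids = sorted({si for ev in detected for si in ev.per_scan})
    scan_total = {
        si: sum(ev.per_scan.get(si, 0.0) for ev in detected) for si in scan_ids
    }
    scored = []
    for cand in candidates:
        expected = cand.expected_event_set
        n_expected = len(cand.expected_events)
        num = 0.0
        den = 0.0
        for si in scan_ids:
            w = scan_total[si]
            if w <= 0 or n_expected == 0:
                continue
            present = [
                pu for pu in expected
                if pu in by_pu and si in by_pu[pu].per_scan
            ]
            coverage = len(present) / n_expected
            explained = sum(by_pu[pu].per_scan[si] for pu in present)
            purity = explained / w
            num += w * coverage * purity
            den += w
        score = num / den if den > 0 else 0.0
        scored.append(replace(cand, score=score))
    total = sum(c.score for c in scored)
    if total > 0:
        scored = [replace(c, probability=c.score / total) for c in scored]
        kept = [c for c in scored if c.probability >= config.probability_floor]
        if kept and len(kept) < len(scored):
            ptot = sum(c.probability for c in kept)
            kept = [replace(c, probability=c.probability / ptot) for c in kept]
        if kept:
            scored = kept
    return scored


def align_replicates(
    per_run: Sequence[tuple[Sequence[RegioCandidate], float]],
) -> list[RegioCandidate]:
    """Merge candidate scores across replicate runs.

    ``per_run`` holds (scored candidates, run total diagnostic intensity)
    pairs.  Scores are averaged weighted by run intensity; a candidate absent
    from a run contributes zero there.  Probabilities are renormalized over
    the merged list.
    """
    if not per_run:
        return []
    weights = [max(w, 0.0) for _, w in per_run]
    wsum = sum(weights)
    if wsum == 0:
        weights = [1.0] * len(per_run)
        wsum = float(len(per_run))
    merged: dict[tuple, RegioCandidate] = {}
    sums: dict[tuple, float] = {}
    for (cands, _), w in zip(per_run, weights):
        for c in cands:
            key = c.expected_events
            if key not in merged:
                merged[key] = replace(c, score=0.0, probability=0.0)
                sums[key] = 0.0
            sums[key] += w * c.score
            if c.chain_ambiguous:
                merged[key].chain_ambiguous = True
    out = []
    total = 0.0
    for key, cand in merged.items():
        score = sums[key] / wsum
        out.append(replace(cand, score=score))
        total += score
    if total > 0:
        out = [replace(c, probability=c.score / total) for c in out]
    return sorted(out, key=lambda c: c.positions)


def candidate_report(
    annotation: LipidAnnotation,
    candidates: Sequence[RegioCandidate],
    detected: Sequence[DetectedEvent],
) -> pd.DataFrame:
    """Tabulate candidates: positions, score, probability, unique events."""
    all_expected: dict[tuple, int] = {}
    for c in candidates:
        for pu in c.expected_event_set:
            all_expected[pu] = all_expected.get(pu, 0) + 1
    detected_scans = {ev.pu: ev.n_scans for ev in detected}
    rows = []
    for c in candidates:
        unique = sorted(
            pu for pu in c.expected_event_set if all_expected[pu] == 1
        )
        n_scans = min(
            (detected_scans.get(pu, 0) for pu in c.expected_event_set),
            default=0,
        )
        rows.append({
            "annotation": str(annotation),
            "candidate_positions": c.label(),
            "score": round(c.score, 6),
            "probability": round(c.probability, 6),
            "unique_events": ";".join(f"p{p}u{u}" for p, u in unique),
            "n_scans_support": n_scans,
        })
    return pd.DataFrame(
        rows,
        columns=["annotation", "candidate_positions", "score", "probability",
                 "unique_events", "n_scans_support"],
    )
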