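"""High-level convenience pipeline: detect -> enumerate -> score -> partition.

One call per lipid annotation over one or more replicate runs; the CLI
``annotate`` command performs exactly these steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .lipid_core import LipidAnnotation
from .oznox_chem import CLASS_RULES, ClassRule, oznox_precursor
from .quantify import IsomerAbundance, partition_abundances
from .regioisomer_engine import (
    DEFAULT_CONFIG,
    DetectedEvent,
    EngineConfig,
    RegioCandidate,
    align_replicates,
    detect_events,
    enumerate_candidates,
    score_candidates,
)
from .spectra_io import Scan, assign_prm_scans

__all__ = ["AnnotationResult", "annotate_lipid"]


@dataclass
class AnnotationResult:
    annotation: LipidAnnotation
    detected: list[DetectedEvent]
    candidates: list[RegioCandidate]
    abundances: list[IsomerAbundance]

    @property
    def status(self) -> str:
        if not self.detected:
            return "not-detected"
        if self.abundances:
            return "confirmed"
        return "candidates-only"

    def abundance_of(self, label: str) -> float:
        """Relative abundance (%) of the isomer with the given label;
        0.0 when absent or pruned."""
        for ab in self.abundances:
            if ab.candidate.label() == label and not ab.pruned:
                return ab.relative_abundance
        return 0.0


def annotate_lipid(
    annotation: LipidAnnotation,
    runs: Sequence[Sequence[Scan]],
    rule: ClassRule | None = None,
    config: EngineConfig = DEFAULT_CONFIG,
    rt: float | None = None,
    rt_window: float = 1.0,
    pruning_floor_pct: float = 1.0,
) -> AnnotationResult:
    """Annotate one lipid's C=C regioisomers across replicate runs."""
    rule = rule or CLASS_RULES[annotation.lipid_class]
    prec_mz = oznox_precursor(annotation, "+", rule).mz
    rt = rt if rt is not None else annotation.retention_time
    window = (
        (rt - rt_window, rt + rt_window) if rt is not None else (-1e12, 1e12)
    )
    per_run = []
    detected_union: dict[tuple[int, int], DetectedEvent] = {}
    for scans in runs:
        prm = assign_prm_scans(scans, prec_mz, window)
        if not prm:
            continue
        det = detect_events(annotation, prm, rule, config)
        for ev in det:
            if ev.pu in detected_union:
                for si, val in ev.per_scan.items():
                    detected_union[ev.pu].per_scan[si] = (
                        detected_union[ev.pu].per_scan.get(si, 0.0) + val
                    )
            else:
                detected_union[ev.pu] = DetectedEvent(
                    ev.p, ev.u, dict(ev.per_scan), dict(ev.per_role)
                )
        cands = enumerate_candidates(annotation, det, config)
        scored = score_candidates(cands, det, config)
        weight = sum(ev.total_intensity for ev in det)
        per_run.append((scored, weight))
    detected = list(detected_union.values())
    merged = align_replicates(per_run) if per_run else []
    abundances: list[IsomerAbundance] = []
    if merged and len(merged) <= config.candidate_cap:
        abundances = partition_abundances(merged, detected, pruning_floor_pct)
    return AnnotationResult(annotation, detected, merged, abundances)
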