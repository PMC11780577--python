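"""Diagnostic-ion detection, candidate enumeration and scoring."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oznox.lipid_core import parse_annotation
from oznox.oznox_chem import oznox_precursor
from oznox.regioisomer_engine import (
    DetectedEvent,
    EngineConfig,
    RegioCandidate,
    align_replicates,
    brute_force_candidates,
    candidate_report,
    detect_events,
    enumerate_candidates,
    score_candidates,
)
from oznox.spectra_io import assign_prm_scans


def _prm(scans_and_ledger, annotation_text, rt=1.0, window=0.5):
    scans, _ = scans_and_ledger
    ann = parse_annotation(annotation_text)
    tmz = oznox_precursor(ann).mz
    return ann, assign_prm_scans(scans, tmz, (rt - window, rt + window))


def _event(p, u, intensity=100.0, scans=(0, 1, 2)):
    per_scan = {s: intensity for s in scans}
    return DetectedEvent(p, u, per_scan, {"ms2_aldehyde": intensity})


class TestDetection:
    def test_pc_22_6_six_events(self, pc_22_6_run):
        ann, prm = _prm(pc_22_6_run, "PC 16:0/22:6")
        det = detect_events(ann, prm)
        assert sorted(ev.pu for ev in det) == [
            (3, 0), (6, 1), (9, 2), (12, 3), (15, 4), (18, 5)
        ]

    def test_seven_coeluting_fa_isomers(self, fa_seven_run):
        ann, prm = _prm(fa_seven_run, "FA 16:1")
        det = detect_events(ann, prm)
        assert sorted(ev.p for ev in det) == [5, 6, 7, 9, 10, 11, 12]
        assert all(ev.u == 0 for ev in det)

    def test_saturated_annotation_detects_nothing(self, pc_22_6_run):
        scans, _ = pc_22_6_run
        ann = parse_annotation("PC 16:0/18:0")
        det = detect_events(ann, [s for s in scans if s.ms_level == 2][:5])
        assert det == []

    def test_no_scans_is_error(self):
        with pytest.raises(ValueError):
            detect_events(parse_annotation("FA 18:1"), [])

    def test_min_scans_threshold(self, pc_22_6_run):
        ann, prm = _prm(pc_22_6_run, "PC 16:0/22:6")
        strict = EngineConfig(min_scans=len(prm) + 1)
        assert detect_events(ann, prm, config=strict) == []


class TestEnumeration:
    def test_unique_chain(self):
        ann = parse_annotation("FA 18:2")
        cands = enumerate_candidates(ann, [_event(6, 0), _event(9, 1)])
        assert [c.positions for c in cands] == [((6, 9),)]

    def test_chaining_admits_cross_pairings(self):
        # events {(6,0),(9,1),(9,0),(12,1)} chain into n-6,9 / n-9,12 / n-6,12
        ann = parse_annotation("FA 18:2")
        det = [_event(6, 0), _event(9, 1), _event(9, 0), _event(12, 1)]
        cands = enumerate_candidates(ann, det)
        assert sorted(c.positions[0] for c in cands) == [
            (6, 9), (6, 12), (9, 12)
        ]

    def test_monounsaturated_single_event(self):
        ann = parse_annotation("FA 18:1")
        cands = enumerate_candidates(ann, [_event(7, 0)])
        assert [c.positions for c in cands] == [((7,),)]

    def test_degenerate_two_chain_events_merge(self):
        """Two chains carrying the same (p, u) give one merged candidate."""
        ann = parse_annotation("PE 16:1_18:1")
        cands = enumerate_candidates(ann, [_event(7, 0)])
        assert len(cands) == 1
        assert cands[0].positions == ((7,), (7,))

    def test_no_valid_candidate_reported_not_raised(self):
        ann = parse_annotation("FA 18:2")
        # u=1 event with no compatible u=0 partner below it
        assert enumerate_candidates(ann, [_event(4, 1)]) == []

    def test_spacing_constraint(self):
        ann = parse_annotation("FA 18:2")
        det = [_event(8, 0), _event(9, 1)]
        assert enumerate_candidates(ann, det) == []

    @given(
        carbons=st.integers(6, 22),
        d=st.integers(1, 3),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_equals_brute_force(self, carbons, d, data):
        """Chaining enumeration equals the exhaustive pattern oracle."""
        if d > (carbons - 2) // 2:
            d = (carbons - 2) // 2
        if d == 0:
            return
        ann = parse_annotation(f"FA {carbons}:{d}")
        pool = [
            (p, u) for u in range(d) for p in range(2, carbons - 1)
        ]
        detected = [
            _event(p, u)
            for p, u in data.draw(
                st.lists(st.sampled_from(pool), max_size=8, unique=True)
            )
        ]
        fast = enumerate_candidates(ann, detected)
        slow = brute_force_candidates(ann, detected)
        assert [c.positions for c in fast] == [c.positions for c in slow]


class TestScoring:
    def test_unique_explainer_scores_one(self):
        ann = parse_annotation("FA 18:1")
        det = [_event(9, 0)]
        cands = score_candidates(enumerate_candidates(ann, det), det)
        assert cands[0].score == pytest.approx(1.0)
        assert cands[0].probability == pytest.approx(1.0)

    def test_purity_split(self):
        # two monounsaturated candidates; one explains 90% of the intensity
        det = [_event(9, 0, 90.0), _event(7, 0, 10.0)]
        ann = parse_annotation("FA 18:1")
        scored = score_candidates(enumerate_candidates(ann, det), det)
        by_pos = {c.positions[0][0]: c for c in scored}
        assert by_pos[9].score == pytest.approx(0.9)
        assert by_pos[7].score == pytest.approx(0.1)

    def test_coverage_fraction(self):
        # candidate expects 4 events, 3 detected in every scan
        cand = RegioCandidate((((3, 6, 9, 12)),))
        cand = RegioCandidate(((3, 6, 9, 12),))
        det = [_event(3, 0), _event(6, 1), _event(9, 2)]
        scored = score_candidates([cand], det)
        # coverage 0.75, purity 1.0 in each scan
        assert scored[0].score == pytest.approx(0.75)

    def test_probabilities_sum_to_one(self, fa_seven_run):
        ann, prm = _prm(fa_seven_run, "FA 16:1")
        det = detect_events(ann, prm)
        scored = score_candidates(enumerate_candidates(ann, det), det)
        assert sum(c.probability for c in scored) == pytest.approx(1.0)

    def test_scale_invariance(self):
        det1 = [_event(9, 0, 90.0), _event(7, 0, 10.0)]
        det2 = [_event(9, 0, 9000.0), _event(7, 0, 1000.0)]
        ann = parse_annotation("FA 18:1")
        s1 = score_candidates(enumerate_candidates(ann, det1), det1)
        s2 = score_candidates(enumerate_candidates(ann, det2), det2)
        for a, b in zip(s1, s2):
            assert a.score == pytest.approx(b.score)

    def test_noiseless_truth_recovers_probability_one(self, pc_22_6_run):
        """On a noiseless single-truth run the true isomer takes p >= 0.99."""
        ann, prm = _prm(pc_22_6_run, "PC 16:0/22:6")
        det = detect_events(ann, prm)
        scored = score_candidates(enumerate_candidates(ann, det), det)
        best = max(scored, key=lambda c: c.probability)
        assert best.positions == ((), (3, 6, 9, 12, 15, 18))
        assert best.probability >= 0.99

    def test_probability_floor_drops_trace_candidates(self):
        det = [_event(9, 0, 999.0), _event(7, 0, 1.0)]
        ann = parse_annotation("FA 18:1")
        scored = score_candidates(enumerate_candidates(ann, det), det)
        assert [c.positions[0][0] for c in scored] == [9]
        assert scored[0].probability == pytest.approx(1.0)


class TestReplicates:
    def _scored(self, ann, det):
        return score_candidates(enumerate_candidates(ann, det), det)

    def test_identical_replicates_unchanged(self):
        ann = parse_annotation("FA 18:1")
        det = [_event(9, 0, 90.0), _event(7, 0, 10.0)]
        scored = self._scored(ann, det)
        merged = align_replicates([(scored, 100.0), (scored, 100.0)])
        for a, b in zip(merged, sorted(scored, key=lambda c: c.positions)):
            assert a.score == pytest.approx(b.score)

    def test_empty_replicate_halves_scores_under_equal_weights(self):
        ann = parse_annotation("FA 18:1")
        det = [_event(9, 0)]
        scored = self._scored(ann, det)
        merged = align_replicates([(scored, 1.0), ([], 1.0)])
        assert merged[0].score == pytest.approx(scored[0].score / 2)

    def test_three_replicates_intensity_weighted_mean(self):
        ann = parse_annotation("FA 18:1")
        runs = []
        weights = [100.0, 300.0, 600.0]
        scores = []
        for w, (i9, i7) in zip(
            weights, [(90.0, 10.0), (80.0, 20.0), (70.0, 30.0)]
        ):
            det = [_event(9, 0, i9), _event(7, 0, i7)]
            scored = self._scored(ann, det)
            scores.append(
                {c.positions[0][0]: c.score for c in scored}
            )
            runs.append((scored, w))
        merged = align_replicates(runs)
        expected_9 = sum(
            w * s[9] for w, s in zip(weights, scores)
        ) / sum(weights)
        got = {c.positions[0][0]: c.score for c in merged}
        assert got[9] == pytest.approx(expected_9)


class TestReport:
    def test_candidate_table_columns_and_unique_events(self):
        ann = parse_annotation("FA 18:2")
        det = [_event(6, 0), _event(9, 1), _event(9, 0), _event(12, 1)]
        scored = score_candidates(enumerate_candidates(ann, det), det)
        df = candidate_report(ann, scored, det)
        assert list(df.columns) == [
            "annotation", "candidate_positions", "score", "probability",
            "unique_events", "n_scans_support",
        ]
        uniq = dict(zip(df["candidate_positions"], df["unique_events"]))
        assert uniq["n-6,12"] == ""      # both its events shared with others
        assert uniq["n-6,9"] == "p9u1"   # (9,1) fits no other candidate
        assert uniq["n-9,12"] == "p9u0"
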