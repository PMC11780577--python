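"""Theoretical ozonolysis / OzNOx product generation and PRM targets."""

import itertools

import pytest

from oznox.lipid_core import composition, formula, parse_annotation
from oznox.oznox_chem import (
    CLASS_RULES,
    CleavageEvent,
    aldehyde_composition,
    build_prm_targets,
    enumerate_cleavages,
    expected_roles,
    legal_pu_events,
    ms2_product,
    nitrate_anion_mz,
    oznox_ms2_products,
    oznox_precursor,
    ozesi_products,
    write_prm_targets,
)


class TestCleavages:
    def test_polyunsaturated_chain(self):
        ann = parse_annotation("FA 22:4(n-6,9,12,15)")
        assert [ev.pu for ev in enumerate_cleavages(ann)] == [
            (6, 0), (9, 1), (12, 2), (15, 3)
        ]

    def test_monounsaturated(self):
        ann = parse_annotation("FA 18:1(n-9)")
        assert [ev.pu for ev in enumerate_cleavages(ann)] == [(9, 0)]

    def test_shared_position_flagged_mass_degenerate(self):
        ann = parse_annotation("PE 16:1(n-7)_18:1(n-7)")
        events = enumerate_cleavages(ann)
        assert [(ev.chain_index, ev.p, ev.u) for ev in events] == [
            (0, 7, 0), (1, 7, 0)
        ]
        assert all(ev.mass_degenerate for ev in events)

    def test_incomplete_positions_rejected(self):
        with pytest.raises(ValueError):
            enumerate_cleavages(parse_annotation("PC 16:0/22:6"))

    def test_legal_events_respect_chaining_bounds(self):
        # FA 18:3: the first C=C (u=0) can sit at n-2..n-12, the last (u=2)
        # at n-6..n-16; every event leaves room for the others
        events = legal_pu_events(parse_annotation("FA 18:3"))
        assert (2, 0) in events and (12, 0) in events and (13, 0) not in events
        assert (6, 2) in events and (5, 2) not in events and (16, 2) in events


class TestOzESIProducts:
    def test_oleate_aldehyde_is_oxononanoate(self):
        # cleaving the n-9 C=C leaves 9-oxononanoic acid
        ann = parse_annotation("FA 18:1(n-9)")
        prods = ozesi_products(ann, include_criegee=False)
        assert len(prods) == 1
        assert aldehyde_composition(ann, prods[0].cleavage) == formula(
            "C9H16O3"
        )
        assert prods[0].mz == pytest.approx(171.1027, abs=1e-4)
        assert prods[0].polarity == "-"

    def test_four_distinct_aldehydes(self):
        ann = parse_annotation("PC 17:0/22:4(n-6,9,12,15)")
        prods = ozesi_products(ann, include_criegee=False)
        assert len({round(p.mz, 6) for p in prods}) == 4

    def test_saturated_lipid_yields_nothing(self):
        assert ozesi_products(parse_annotation("PC 16:0/18:0")) == []

    def test_criegee_is_aldehyde_plus_oxygen(self):
        prods = ozesi_products(parse_annotation("FA 18:1(n-9)"))
        by_role = {p.role: p for p in prods}
        assert by_role["ozesi_criegee"].mz - by_role[
            "ozesi_aldehyde"
        ].mz == pytest.approx(15.9949, abs=1e-4)

    def test_mass_degenerate_cleavages_deduplicated(self):
        prods = ozesi_products(
            parse_annotation("PE 16:1(n-7)_18:1(n-7)"), include_criegee=False
        )
        assert len(prods) == 1


class TestOzNOxPrecursor:
    def test_single_mz_despite_four_double_bonds(self):
        ann = parse_annotation("PC 17:0/22:4(n-6,9,12,15)")
        prod = oznox_precursor(ann, "+")
        assert isinstance(prod.mz, float)
        # the adduct is an ensemble over all C=C with one m/z
        neutral = composition(ann)
        assert prod.mz == pytest.approx(
            neutral.mass + 77.98273 - 1.00783 - 0.00055, abs=1e-3
        )

    def test_position_independent(self):
        a = oznox_precursor(parse_annotation("FA 22:4(n-6,9,12,15)"))
        b = oznox_precursor(parse_annotation("FA 22:4(n-4,9,12,17)"))
        assert a.mz == b.mz

    def test_saturated_is_error(self):
        with pytest.raises(ValueError):
            oznox_precursor(parse_annotation("PC 16:0/18:0"))

    def test_negative_mode_adduct(self):
        ann = parse_annotation("FA 18:1(n-9)")
        neg = oznox_precursor(ann, "-")
        assert neg.polarity == "-"
        assert neg.mz == pytest.approx(
            composition(ann).mass + 2 * 14.00307 + 7 * 15.99491 + 0.00055,
            abs=1e-3,
        )

    def test_ammonium_classes_adduct_includes_ammonia(self):
        pg = parse_annotation("PG 16:0/18:1(n-9)")
        ps = parse_annotation("PS 16:0/18:1(n-9)")
        diff = oznox_precursor(pg).mz - oznox_precursor(ps).mz
        core_diff = (
            composition(pg).mass - composition(ps).mass
        )
        assert diff - core_diff == pytest.approx(17.02655, abs=1e-4)


class TestMS2Products:
    @pytest.mark.parametrize(
        "text, per_cleavage",
        [
            ("PC 16:0/18:1(n-9)", 2),     # pair
            ("LPE 18:2(n-6,9)", 3),       # triplet with water loss
            ("FA 18:1(n-9)", 3),          # ammoniated / protonated / -H2O
            ("PE 16:0/18:1(n-9)", 4),     # pair with and without headgroup
        ],
    )
    def test_products_per_double_bond(self, text, per_cleavage):
        ann = parse_annotation(text)
        prods = oznox_ms2_products(ann)
        n_cleavages = len(enumerate_cleavages(ann))
        assert len(prods) == per_cleavage * n_cleavages

    def test_cross_class_convergence(self):
        """PE/PG/PI/PS/PA/LPG with the same acyls give identical
        headgroup-lost diagnostic m/z, regardless of base adduct."""
        mz_sets = []
        for cls in ("PE", "PG", "PI", "PS", "PA"):
            ann = parse_annotation(f"{cls} 16:0/18:2(n-6,9)")
            prods = [
                p for p in oznox_ms2_products(ann)
                if p.role in ("ms2_aldehyde", "ms2_aldehyde_minus_CHO")
            ]
            mz_sets.append(sorted(p.mz for p in prods))
        for other in mz_sets[1:]:
            assert all(
                abs(a - b) < 1e-6 for a, b in zip(mz_sets[0], other)
            )

    def test_lyso_convergence_lpg_vs_lpe_differs_only_by_scheme(self):
        lpg = parse_annotation("LPG 18:1(n-9)")
        prods = oznox_ms2_products(lpg)
        assert len(prods) == 2  # headgroup-lost pair

    def test_pc_ms2_aldehyde_equals_ozesi_aldehyde(self):
        ann = parse_annotation("PC 16:0/22:6(n-3,6,9,12,15,18)")
        ozesi = {
            round(p.mz, 6)
            for p in ozesi_products(ann, include_criegee=False)
        }
        ms2 = {
            round(p.mz, 6)
            for p in oznox_ms2_products(ann)
            if p.role == "ms2_aldehyde"
        }
        assert ms2 == ozesi

    def test_radical_companion_is_cho_below_aldehyde(self):
        ann = parse_annotation("PC 16:0/18:1(n-9)")
        by_role = {p.role: p for p in oznox_ms2_products(ann)}
        assert by_role["ms2_aldehyde"].mz - by_role[
            "ms2_aldehyde_minus_CHO"
        ].mz == pytest.approx(29.0027, abs=1e-4)

    def test_aldehyde_collision_across_species(self):
        """The n-15 aldehyde of LPC 22:4(n-6,9,12,15) is formula-identical
        to the n-11 aldehyde of LPC 18:1(n-11)."""
        a = aldehyde_composition(
            parse_annotation("LPC 22:4(n-6,9,12,15)"), CleavageEvent(0, 15, 3)
        )
        b = aldehyde_composition(
            parse_annotation("LPC 18:1(n-11)"), CleavageEvent(0, 11, 0)
        )
        assert a == b

    def test_aldehyde_mz_monotone_in_p_and_u(self):
        # cleaving further from the methyl end (larger p) sheds a larger
        # methyl-side fragment, so aldehyde m/z strictly decreases in p;
        # each methyl-side C=C retained (larger u) keeps two H, so m/z
        # strictly increases in u
        ann = parse_annotation("FA 22:4")
        rule = CLASS_RULES["FA"]
        for u in (0, 1):
            mzs = [
                ms2_product(ann, rule, "ms2_aldehyde", p, u).mz
                for p in range(4 + 2 * u, 16)
            ]
            assert mzs == sorted(mzs, reverse=True)
            assert len(set(mzs)) == len(mzs)
        for p in (10, 12):
            mzs = [
                ms2_product(ann, rule, "ms2_aldehyde", p, u).mz
                for u in range(0, 3)
            ]
            assert mzs == sorted(mzs)

    def test_nitrate_dominates_negative_ms2(self):
        assert f"{nitrate_anion_mz():.2f}" == "61.99"


class TestRuleOverrides:
    def test_json_config_overrides_nce_and_adduct(self, tmp_path):
        import json

        from oznox.oznox_chem import load_class_rules

        cfg = tmp_path / "rules.json"
        cfg.write_text(json.dumps({
            "PC": {"nce": 18},
            "PG": {"ammoniated_precursor": False},
        }))
        rules = load_class_rules(cfg)
        assert rules["PC"].nce == 18
        assert not rules["PG"].ammoniated_precursor
        assert rules["PE"].nce == CLASS_RULES["PE"].nce  # untouched

    def test_unknown_class_rejected(self, tmp_path):
        import json

        from oznox.oznox_chem import load_class_rules

        cfg = tmp_path / "rules.json"
        cfg.write_text(json.dumps({"TG": {"nce": 20}}))
        with pytest.raises(ValueError):
            load_class_rules(cfg)


class TestPRMTargets:
    def _anns(self):
        return [
            parse_annotation(t).with_rt(rt)
            for t, rt in [
                ("FA 18:1(n-9)", 3.0),
                ("PE 16:0/18:1(n-9)", 2.0),
                ("PC 16:0/22:6(n-3,6,9,12,15,18)", 1.0),
            ]
        ]

    def test_one_target_per_annotation_sorted_by_rt(self):
        targets = build_prm_targets(self._anns(), rt_window_min=0.5)
        assert len(targets) == 3
        assert [t.annotation.lipid_class for t in targets] == [
            "PC", "PE", "FA"
        ]
        assert all(t.rt_end - t.rt_start == pytest.approx(1.0)
                   for t in targets)

    def test_class_collision_energies(self):
        nce = {
            t.annotation.lipid_class: t.nce
            for t in build_prm_targets(self._anns())
        }
        assert nce == {"FA": 10, "PE": 25, "PC": 15}

    def test_missing_rt_is_error(self):
        with pytest.raises(ValueError):
            build_prm_targets([parse_annotation("FA 18:1(n-9)")])

    def test_saturated_is_error(self):
        with pytest.raises(ValueError):
            build_prm_targets([parse_annotation("FA 18:0").with_rt(1.0)])

    def test_target_tsv_shape(self, tmp_path):
        import pandas as pd

        path = tmp_path / "targets.tsv"
        write_prm_targets(build_prm_targets(self._anns()), path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == [
            "mz", "polarity", "rt_start_min", "rt_end_min", "nce",
            "annotation",
        ]
        assert len(df) == 3
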