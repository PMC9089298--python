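"""ITS engine: scoping, filtering, prioritization, iteration, reporting."""

import random

import pytest

from nanoits.dossier import WHOLE_NM, create_nhp, set_classification
from nanoits.fixtures import generate_random_dossier, generate_random_kb
from nanoits.its import (
    filter_assays,
    its_step,
    priority_score,
    rank_assays,
    select_scope,
)
from nanoits.kb import CharacteristicProfile
from nanoits.report import export_report


def mp(route, systemic=None):
    props = {"clinical_indication": "other", "administration_route": route}
    if systemic is not None:
        props["dermal_systemic_exposure"] = systemic
    return create_nhp("probe", "medicinal_product", props)


class TestSelectScope:
    def test_dermal_no_systemic_keeps_skin_sensitisation_in_scope(self, kb):
        pairs = select_scope(kb, mp("dermal", systemic="no"))
        assert ("immunotoxicity", "skin_sensitisation") in pairs

    def test_intravenous_route_drops_skin_sensitisation(self, kb):
        pairs = select_scope(kb, mp("intravenous"))
        assert ("immunotoxicity", "skin_sensitisation") not in pairs
        # the rest of the immunotoxicity module stays in scope
        assert ("immunotoxicity", "sts_haematological_changes") in pairs

    def test_dermal_with_unknown_systemic_exposure_stays_in_scope(self, kb):
        assert ("immunotoxicity", "skin_sensitisation") in select_scope(kb, mp("dermal"))

    def test_kb_without_selection_rules_scopes_everything(self):
        rkb = generate_random_kb(seed=7, n_endpoints=4, n_assays=2)
        dossier = generate_random_dossier(1, rkb, 0.5)
        pairs = select_scope(rkb, dossier)
        assert pairs == [("module_0", e.id) for e in rkb.endpoints]


class TestFilterAssays:
    def test_empty_dossier_excludes_nothing(self, kb, empty_dossier):
        verdicts = filter_assays(kb, empty_dossier, WHOLE_NM, "particle_size_lower")
        assert len(verdicts) == 6
        assert all(v.verdict != "excluded" for v in verdicts)

    def test_ionp_exclusions_and_reasons(self, kb, ionp):
        verdicts = {v.assay_id: v for v in filter_assays(kb, ionp, WHOLE_NM, "particle_size_lower")}
        assert verdicts["nta"].verdict == "applicable"
        for fractionation in ("sec_uv_vis_ri", "af4_uv_vis_ri", "cf3_uv_vis_ri"):
            assert verdicts[fractionation].verdict == "excluded"
            assert [a.endpoint_id for a in verdicts[fractionation].exclusion_reasons] == [
                "particle_classification"
            ]
        assert verdicts["dls"].verdict == "excluded"
        assert [a.endpoint_id for a in verdicts["dls"].exclusion_reasons] == ["polydispersity"]
        assert verdicts["sls"].verdict == "excluded"
        assert [a.endpoint_id for a in verdicts["sls"].exclusion_reasons] == ["particle_size_lower"]

    def test_iron_carbohydrate_keeps_only_dls(self, kb, iron_carbohydrate):
        verdicts = {
            v.assay_id: v
            for v in filter_assays(kb, iron_carbohydrate, WHOLE_NM, "particle_size_lower")
        }
        assert verdicts["dls"].verdict == "applicable"
        assert verdicts["nta"].verdict == "excluded"
        assert {a.endpoint_id for a in verdicts["nta"].exclusion_reasons} == {
            "particle_size_lower"
        }

    def test_verdict_trace_agrees_with_rule_evaluation(self, kb, ionp):
        from nanoits.rules import eval_rule

        for v in filter_assays(kb, ionp, WHOLE_NM, "particle_size_lower"):
            rule = kb.get_assay(v.assay_id).applicability
            if rule is None:
                continue
            assert v.trace.value is eval_rule(rule, ionp.effective_facts(), kb)


class TestPriority:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            (("low", "low", "high", "low"), 3),
            (("high", "high", "low", "high"), 11),
            (("medium", "medium", "medium", "medium"), 7),
        ],
    )
    def test_formula_addends(self, profile, expected):
        assert priority_score(CharacteristicProfile(*profile)) == expected

    def test_score_bounds_over_all_profiles(self):
        levels = ("low", "medium", "high")
        scores = {
            priority_score(CharacteristicProfile(d, c, r, e))
            for d in levels for c in levels for r in levels for e in levels
        }
        assert min(scores) == 3 and max(scores) == 11

    def test_worsening_one_characteristic_never_improves_the_score(self):
        levels = ("low", "medium", "high")
        for d in levels:
            for c in levels:
                for r in levels:
                    for e in levels:
                        base = priority_score(CharacteristicProfile(d, c, r, e))
                        for i, worse in enumerate(
                            [levels[min(levels.index(x) + 1, 2)] for x in (d, c, e)]
                        ):
                            fields = [d, c, r, e]
                            fields[[0, 1, 3][i]] = worse
                            assert priority_score(CharacteristicProfile(*fields)) >= base
                        better_res = levels[max(levels.index(r) - 1, 0)]
                        assert priority_score(CharacteristicProfile(d, c, better_res, e)) >= base


class TestRanking:
    def test_dls_and_sls_lead_the_empty_low_resolution_group(self, kb, empty_dossier):
        verdicts = filter_assays(kb, empty_dossier, WHOLE_NM, "particle_size_lower")
        ranked = [r for r in rank_assays(kb, verdicts) if r.resolution_group == "low"]
        assert [r.assay_id for r in ranked[:2]] == ["dls", "sls"]
        assert [r.rank for r in ranked] == list(range(1, len(ranked) + 1))

    def test_equal_profiles_break_ties_by_id(self):
        rkb = generate_random_kb(seed=5, n_endpoints=2, n_assays=0)
        from nanoits.kb import AssayDef

        profile = CharacteristicProfile("low", "low", "low", "low")
        for aid in ("zeta", "alpha"):
            rkb = rkb.with_assay(
                AssayDef(aid, aid, "module_0", (rkb.endpoints[0].id,), profile)
            )
        dossier = generate_random_dossier(1, rkb, 0.0)
        verdicts = filter_assays(rkb, dossier, WHOLE_NM, rkb.endpoints[0].id)
        ranked = rank_assays(rkb, verdicts)
        by_group = [r for r in ranked if r.resolution_group == "low"]
        assert [r.assay_id for r in by_group] == ["alpha", "zeta"]
        assert [r.rank for r in by_group] == [1, 2]

    def test_excluded_verdict_rejected(self, kb, ionp):
        verdicts = filter_assays(kb, ionp, WHOLE_NM, "particle_size_lower")
        with pytest.raises(ValueError):
            rank_assays(kb, verdicts)


class TestITSStep:
    def test_completeness_partition_for_every_entry(self, kb):
        for name in ("empty", "ionp", "iron_carbohydrate", "liposome", "paca"):
            from nanoits.fixtures import dossier_fixture

            result = its_step(kb, dossier_fixture(name))
            for entry in result.entries:
                expected = len(kb.assays_measuring(entry.endpoint_id))
                assert len(entry.ranked) + len(entry.excluded) == expected
                ids = {r.assay_id for r in entry.ranked} | {v.assay_id for v in entry.excluded}
                assert len(ids) == expected

    def test_ionp_low_resolution_size_list_is_nta_alone(self, kb, ionp):
        entry = its_step(kb, ionp).lookup(WHOLE_NM, "particle_size_lower")
        assert [r.assay_id for r in entry.group("low")] == ["nta"]
        assert len(entry.excluded) == 5
        assert all(v.trace is not None for v in entry.excluded)

    def test_deterministic_across_repeated_runs(self, kb, ionp):
        from nanoits.report import result_to_dict

        first = result_to_dict(its_step(kb, ionp), kb)
        second = result_to_dict(its_step(kb, ionp), kb)
        assert first == second

    def test_component_scopes_are_assessed_separately(self, kb, ionp):
        result = its_step(kb, ionp)
        scopes = {e.scope for e in result.entries}
        assert scopes == {WHOLE_NM, "magnetite_core", "maghemite_core", "dextran_matrix"}
        # the component dossiers carry no facts, so nothing is excluded there
        comp_entry = result.lookup("dextran_matrix", "particle_size_lower")
        assert comp_entry.excluded == []

    def test_monotone_filtering_under_random_fact_growth(self, kb):
        """Acquiring knowledge can only shrink the candidate list."""
        rng = random.Random(20240)
        assignable = [
            e for e in kb.endpoints
            if e.module_id == "physicochemical"
        ]
        for trial in range(20):
            dossier = create_nhp(
                f"t{trial}", "medicinal_product",
                {"clinical_indication": "other", "administration_route": "intravenous"},
            )
            excluded_so_far = set()
            order = rng.sample(assignable, len(assignable))
            for endpoint in order:
                set_classification(
                    dossier, kb, WHOLE_NM, endpoint.id,
                    rng.choice(endpoint.class_labels()),
                )
                verdicts = filter_assays(kb, dossier, WHOLE_NM, "particle_size_lower")
                now_excluded = {v.assay_id for v in verdicts if v.verdict == "excluded"}
                assert excluded_so_far <= now_excluded
                excluded_so_far = now_excluded


class TestReport:
    def test_ionp_report_cites_polydispersity_for_dls(self, kb, ionp):
        doc = export_report(its_step(kb, ionp), kb, "markdown")
        dls_lines = [l for l in doc.splitlines() if l.strip().startswith("- dls:")]
        assert any("polydispersity" in l for l in dls_lines)

    def test_iron_carbohydrate_report_cites_size_for_sls(self, kb, iron_carbohydrate):
        doc = export_report(its_step(kb, iron_carbohydrate), kb, "text")
        sls_lines = [l for l in doc.splitlines() if l.strip().startswith("sls:")]
        assert any("particle_size" in l for l in sls_lines)

    def test_empty_report_states_no_exclusions(self, kb, empty_dossier):
        doc = export_report(its_step(kb, empty_dossier), kb, "text")
        assert "No exclusions" in doc

    def test_report_shows_all_four_addends(self, kb, empty_dossier):
        doc = export_report(its_step(kb, empty_dossier), kb, "text")
        assert "duration 1 + cost 1 + (3-resolution) 2 + expertise 1" in doc

    def test_json_export_is_stable_and_parseable(self, kb, ionp):
        import json

        doc = export_report(its_step(kb, ionp), kb, "json")
        payload = json.loads(doc)
        rerendered = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        assert rerendered == doc

    def test_unsupported_format_rejected(self, kb, ionp):
        with pytest.raises(ValueError, match="format"):
            export_report(its_step(kb, ionp), kb, "pdf")
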