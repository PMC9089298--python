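"""Three-valued rule evaluation: Kleene semantics, oracle soundness, traces."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoits.fixtures import generate_random_kb, generate_random_rule, random_fact_state
from nanoits.rules import (
    Atom,
    FactState,
    RuleExpr,
    TruthValue,
    eval_atom,
    eval_rule,
    eval_rule_oracle,
    explain,
    false_atoms,
    rule_from_dict,
    rule_to_dict,
)

T, F, U = TruthValue.TRUE, TruthValue.FALSE, TruthValue.UNKNOWN


def nta_rule(kb):
    return kb.get_assay("nta").applicability


class TestAtoms:
    def test_class_is_matches_assigned_class(self, kb):
        atom = Atom("class_is", "refractive_index", "low_ri")
        assert eval_atom(atom, FactState({"refractive_index": "low_ri"}), kb) is T
        assert eval_atom(atom, FactState({"refractive_index": "high_ri"}), kb) is F

    def test_unassigned_endpoint_is_unknown(self, kb):
        atom = Atom("class_is", "formulation", "liquid")
        assert eval_atom(atom, FactState(), kb) is U

    def test_class_in_membership(self, kb):
        atom = Atom("class_in", "particle_size_lower", frozenset({"small", "mid_low"}))
        assert eval_atom(atom, FactState({"particle_size_lower": "small"}), kb) is T
        assert eval_atom(atom, FactState({"particle_size_lower": "big"}), kb) is F

    def test_range_atom_from_class_bin(self, kb):
        # bin [0, 30) is disjoint from [60, 1000] -> definite FALSE
        atom = Atom("range_within", "particle_size_lower", (60, 1000))
        assert eval_atom(atom, FactState({"particle_size_lower": "small"}), kb) is F
        # bin [60, 200) is contained in [60, 1000] -> definite TRUE
        assert eval_atom(atom, FactState({"particle_size_lower": "mid_high"}), kb) is T
        # bin [200, 10000] straddles the upper edge -> UNKNOWN
        assert eval_atom(atom, FactState({"particle_size_lower": "big"}), kb) is U

    def test_range_atom_prefers_numeric_value(self, kb):
        atom = Atom("range_within", "particle_size_lower", (60, 1000))
        facts = FactState({"particle_size_lower": "big"}, values={"particle_size_lower": 900})
        assert eval_atom(atom, facts, kb) is T

    def test_unknown_endpoint_raises(self, kb):
        with pytest.raises(Exception):
            eval_atom(Atom("class_is", "nope", "x"), FactState(), kb)


class TestRuleEvaluation:
    def test_nta_rule_true_on_compatible_facts(self, kb):
        facts = FactState({"refractive_index": "low_ri", "particle_size_lower": "mid_high"})
        assert eval_rule(nta_rule(kb), facts, kb) is T

    def test_skin_sensitisation_rule_true_on_dermal_no_systemic(self, kb):
        rule = kb.get_assay("oecd_442c").applicability
        facts = FactState({"route_of_administration": "dermal", "dermal_systemic_exposure": "no"})
        assert eval_rule(rule, facts, kb) is T
        assert eval_rule(rule, FactState({"route_of_administration": "intravenous"}), kb) is F

    def test_empty_facts_give_unknown(self, kb):
        for assay_id in ("nta", "dls", "sls", "oecd_442c"):
            rule = kb.get_assay(assay_id).applicability
            assert eval_rule(rule, FactState(), kb) is U

    @pytest.mark.parametrize(
        "a,b,expected_and,expected_or",
        [(T, T, T, T), (T, U, U, T), (T, F, F, T), (U, U, U, U), (U, F, F, U), (F, F, F, F)],
    )
    def test_kleene_connective_tables(self, a, b, expected_and, expected_or):
        assert min(a, b) is expected_and
        assert max(a, b) is expected_or
        assert ~a is {T: F, F: T, U: U}[a]


class TestOracle:
    def test_matches_eval_rule_on_fully_assigned_facts(self, kb):
        facts = FactState({"refractive_index": "low_ri", "particle_size_lower": "mid_high"})
        rule = nta_rule(kb)
        assert eval_rule_oracle(rule, facts, kb) is eval_rule(rule, facts, kb)

    def test_tautology_resolved_by_oracle_not_by_kleene(self, kb):
        a = RuleExpr.of(Atom("class_is", "formulation", "liquid"))
        tautology = RuleExpr.any(a, RuleExpr.negate(a))
        assert eval_rule(tautology, FactState(), kb) is U
        assert eval_rule_oracle(tautology, FactState(), kb) is T

    def test_nta_true_for_any_ri_when_size_in_window(self, kb):
        # with size fixed in [60, 1000] both refractive-index completions
        # satisfy one branch of the rule
        facts = FactState({"particle_size_lower": "mid_high"})
        assert eval_rule(nta_rule(kb), facts, kb) is U
        assert eval_rule_oracle(nta_rule(kb), facts, kb) is T


class TestExplain:
    def test_trace_root_matches_eval_and_first_branch_shows_ri(self, kb, ionp):
        facts = ionp.scope_facts()
        trace = explain(nta_rule(kb), facts, kb)
        assert trace.value is eval_rule(nta_rule(kb), facts, kb) is T
        ri_atoms = [
            n for branch in trace.children for n in branch.children
            if n.atom is not None and n.atom.endpoint_id == "refractive_index"
        ]
        assert any(n.value is T for n in ri_atoms)
        assert any("high_ri" in n.observed for n in ri_atoms)

    def test_empty_facts_annotate_every_node_unknown(self, kb):
        trace = explain(nta_rule(kb), FactState(), kb)

        def walk(node):
            assert node.value is U
            for c in node.children:
                walk(c)

        walk(trace)

    def test_contradicted_atom_records_observed_class(self, kb):
        expr = RuleExpr.of(Atom("class_is", "formulation", "liquid"))
        trace = explain(expr, FactState({"formulation": "powder"}), kb)
        assert trace.value is F
        assert trace.observed == frozenset({"powder"})
        assert [a.endpoint_id for a, neg in false_atoms(trace)] == ["formulation"]

    def test_blame_crosses_negation_with_polarity(self, kb):
        expr = RuleExpr.negate(RuleExpr.of(Atom("class_is", "formulation", "liquid")))
        trace = explain(expr, FactState({"formulation": "liquid"}), kb)
        assert trace.value is F
        assert false_atoms(trace) == [(expr.not_.atom, True)]


class TestSerialization:
    def test_round_trip_of_every_packaged_rule(self, kb):
        for assay in kb.assays:
            if assay.applicability is None:
                continue
            d = rule_to_dict(assay.applicability)
            assert rule_from_dict(d) == assay.applicability

    def test_malformed_nodes_rejected(self):
        with pytest.raises(Exception):
            rule_from_dict({"xor": []})
        with pytest.raises(Exception):
            RuleExpr(and_=(RuleExpr.of(Atom("class_is", "e", "x")),))  # < 2 children


# ---------------------------------------------------------------------------
# property tests (derandomised via explicit seeds)
# ---------------------------------------------------------------------------

_KB = generate_random_kb(seed=2024, n_endpoints=5, n_assays=0)


@st.composite
def rule_and_facts(draw):
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    completeness = draw(st.sampled_from([0.0, 0.3, 0.6, 1.0]))
    rng = random.Random(seed)
    expr = generate_random_rule(rng, _KB, max_depth=3)
    facts = random_fact_state(rng, _KB, completeness)
    return expr, facts


@settings(max_examples=300, deadline=None, derandomize=True)
@given(rule_and_facts())
def test_kleene_is_sound_versus_enumeration_oracle(pair):
    """A definite Kleene verdict is never contradicted by full enumeration."""
    expr, facts = pair
    kleene = eval_rule(expr, facts, _KB)
    oracle = eval_rule_oracle(expr, facts, _KB)
    if kleene is not U:
        assert oracle is kleene


@settings(max_examples=200, deadline=None, derandomize=True)
@given(rule_and_facts())
def test_de_morgan_laws_hold_under_kleene(pair):
    expr, facts = pair
    if expr.and_ is None:
        expr = RuleExpr.all(expr, expr) if expr.or_ is None else RuleExpr(and_=expr.or_)
    neg_of_and = RuleExpr.negate(expr)
    or_of_negs = RuleExpr(or_=tuple(RuleExpr.negate(c) for c in expr.and_))
    assert eval_rule(neg_of_and, facts, _KB) is eval_rule(or_of_negs, facts, _KB)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_definite_verdicts_survive_knowledge_growth(seed):
    """Extending the fact state never flips a TRUE or FALSE verdict."""
    rng = random.Random(seed)
    expr = generate_random_rule(rng, _KB, max_depth=3)
    sparse = random_fact_state(rng, _KB, 0.3)
    dense = FactState()
    dense.classes = dict(sparse.classes)
    for endpoint in _KB.endpoints:
        if endpoint.id not in dense.classes and rng.random() < 0.7:
            dense.assign(endpoint.id, rng.choice(endpoint.class_labels()))
    assert FactState(dense.classes).extends(sparse)
    before = eval_rule(expr, sparse, _KB)
    after = eval_rule(expr, dense, _KB)
    if before is not U:
        assert after is before
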