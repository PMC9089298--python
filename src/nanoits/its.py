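"""Intelligent testing strategy (ITS) engine.

One ITS step takes a knowledge base and a dossier and produces, for every
in-scope (scope, module, endpoint) triple, a prioritized list of candidate
assays plus the assays excluded by their applicability rules, each with a
full decision trace.  The loop the user runs is: inspect the recommendation,
perform the best assay, record its results, derive/assert the new class,
and re-run the step; the engine itself is stateless and deterministic, and
the decision when to stop is left to the user.

Filtering is deliberately conservative: an assay is excluded only when its
rule is *known* false.  A rule left UNKNOWN by missing facts keeps the assay
in the ranked list, flagged ``possibly_applicable`` -- with an empty dossier
the full assay catalogue is therefore proposed.

Prioritization uses the four ordinal characteristics, each scored
low=1 / medium=2 / high=3:

    priority = duration + cost + (3 - resolution) + expertise

Lower is better: short, cheap, low-expertise assays with high resolution
come first.  The score is bounded in [3, 11].  Assays are presented in two
resolution groups (low vs medium-high), ranked within each group, with the
assay id as the deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .dossier import NHPDossier, WHOLE_NM
from .kb import CharacteristicProfile, KnowledgeBase, characteristic_score
from .rules import TraceNode, TruthValue, eval_rule, explain, false_atoms

__all__ = [
    "AssayVerdict",
    "RankedAssay",
    "EndpointResult",
    "ITSResult",
    "select_scope",
    "filter_assays",
    "priority_score",
    "rank_assays",
    "its_step",
]


@dataclass
class AssayVerdict:
    """Outcome of one assay's applicability rule, with its decision trace."""

    assay_id: str
    verdict: str  # "applicable" | "excluded" | "possibly_applicable"
    trace: Optional[TraceNode] = None  # None for rule-free assays

    @property
    def exclusion_reasons(self) -> list:
        """Atoms to blame for the exclusion (without negation context)."""
        return [] if self.trace is None else [a for a, _ in false_atoms(self.trace)]

    @property
    def exclusion_reasons_with_polarity(self) -> list:
        """(atom, negated) pairs to blame for the exclusion."""
        return [] if self.trace is None else false_atoms(self.trace)


@dataclass
class RankedAssay:
    assay_id: str
    priority: int
    resolution_group: str  # "low" | "medium_high"
    rank: int  # 1-based, dense within the group
    verdict: str  # "applicable" | "possibly_applicable"
    breakdown: Dict[str, int] = field(default_factory=dict)  # four addends


@dataclass
class EndpointResult:
    """Ranked + excluded assays for one (scope, module, endpoint)."""

    scope: str
    module_id: str
    endpoint_id: str
    ranked: List[RankedAssay] = field(default_factory=list)
    excluded: List[AssayVerdict] = field(default_factory=list)

    def group(self, resolution_group: str) -> List[RankedAssay]:
        return [r for r in self.ranked if r.resolution_group == resolution_group]


@dataclass
class ITSResult:
    entries: List[EndpointResult] = field(default_factory=list)

    def lookup(
        self, scope: str, endpoint_id: str, module_id: Optional[str] = None
    ) -> EndpointResult:
        for e in self.entries:
            if (
                e.scope == scope
                and e.endpoint_id == endpoint_id
                and (module_id is None or e.module_id == module_id)
            ):
                return e
        raise KeyError(f"no result for scope={scope!r} endpoint={endpoint_id!r}")


# ---------------------------------------------------------------------------


def select_scope(kb: KnowledgeBase, dossier: NHPDossier) -> List[Tuple[str, str]]:
    """(module, endpoint) pairs to assess for this product.

    A module is in scope when its product_scope admits the product type and
    no module-level selection rule is known false; endpoints inherit the
    module's scope unless an endpoint-level rule is known false.  Rules are
    evaluated over product-level and whole-nanomaterial facts, so with
    incomplete knowledge (UNKNOWN) the scope stays wide.
    """
    facts = dossier.effective_facts(WHOLE_NM)
    module_rules = {r.target_id: r.rule for r in kb.module_selection_rules if any(m.id == r.target_id for m in kb.modules)}
    endpoint_rules = {r.target_id: r.rule for r in kb.module_selection_rules if kb.has_endpoint(r.target_id)}

    out: List[Tuple[str, str]] = []
    for module in kb.modules:
        if dossier.product_type not in module.product_scope:
            continue
        rule = module_rules.get(module.id)
        if rule is not None and eval_rule(rule, facts, kb) is TruthValue.FALSE:
            continue
        for endpoint in kb.endpoints:
            if endpoint.module_id != module.id:
                continue
            erule = endpoint_rules.get(endpoint.id)
            if erule is not None and eval_rule(erule, facts, kb) is TruthValue.FALSE:
                continue
            out.append((module.id, endpoint.id))
    return out


def filter_assays(
    kb: KnowledgeBase,
    dossier: NHPDossier,
    scope: str,
    endpoint_id: str,
) -> List[AssayVerdict]:
    """Verdict per assay measuring the endpoint; excluded only on known FALSE."""
    kb.get_endpoint(endpoint_id)
    facts = dossier.effective_facts(scope)
    verdicts: List[AssayVerdict] = []
    for assay in sorted(kb.assays_measuring(endpoint_id), key=lambda a: a.id):
        if assay.applicability is None:
            verdicts.append(AssayVerdict(assay.id, "applicable", None))
            continue
        trace = explain(assay.applicability, facts, kb)
        verdict = {
            TruthValue.TRUE: "applicable",
            TruthValue.FALSE: "excluded",
            TruthValue.UNKNOWN: "possibly_applicable",
        }[trace.value]
        verdicts.append(AssayVerdict(assay.id, verdict, trace))
    return verdicts


def priority_score(profile: CharacteristicProfile) -> int:
    """duration + cost + (3 - resolution) + expertise over the 1/2/3 scores."""
    return (
        characteristic_score(profile.duration)
        + characteristic_score(profile.cost)
        + (3 - characteristic_score(profile.resolution))
        + characteristic_score(profile.expertise)
    )


def _score_breakdown(profile: CharacteristicProfile) -> Dict[str, int]:
    return {
        "duration": characteristic_score(profile.duration),
        "cost": characteristic_score(profile.cost),
        "resolution_penalty": 3 - characteristic_score(profile.resolution),
        "expertise": characteristic_score(profile.expertise),
    }


def rank_assays(kb: KnowledgeBase, verdicts: List[AssayVerdict]) -> List[RankedAssay]:
    """Rank non-excluded assays within the two resolution groups.

    Ascending priority (lower is better), ties broken by assay id; ranks are
    1-based and dense per group.  Assays whose rule is still UNKNOWN are
    ranked alongside the applicable ones but keep their
    ``possibly_applicable`` flag.
    """
    ranked: List[RankedAssay] = []
    for group_name, members in _partition_by_resolution(kb, verdicts).items():
        members.sort(key=lambda av: (priority_score(_profile(kb, av)), av.assay_id))
        for i, av in enumerate(members, start=1):
            profile = _profile(kb, av)
            ranked.append(
                RankedAssay(
                    assay_id=av.assay_id,
                    priority=priority_score(profile),
                    resolution_group=group_name,
                    rank=i,
                    verdict=av.verdict,
                    breakdown=_score_breakdown(profile),
                )
            )
    return ranked


def _profile(kb: KnowledgeBase, av: AssayVerdict) -> CharacteristicProfile:
    return kb.get_assay(av.assay_id).characteristics


def _partition_by_resolution(
    kb: KnowledgeBase, verdicts: List[AssayVerdict]
) -> Dict[str, List[AssayVerdict]]:
    groups: Dict[str, List[AssayVerdict]] = {"low": [], "medium_high": []}
    for av in verdicts:
        if av.verdict == "excluded":
            raise ValueError(f"excluded assay {av.assay_id!r} passed to rank_assays")
        resolution = _profile(kb, av).resolution
        groups["low" if resolution == "low" else "medium_high"].append(av)
    return groups


def its_step(kb: KnowledgeBase, dossier: NHPDossier) -> ITSResult:
    """One full iteration: scope selection, filtering, ranking.

    Computed for the whole nanomaterial and for each component separately;
    deterministic given (kb, dossier).
    """
    result = ITSResult()
    scope_pairs = select_scope(kb, dossier)
    for scope in dossier.scopes():
        for module_id, endpoint_id in scope_pairs:
            verdicts = filter_assays(kb, dossier, scope, endpoint_id)
            if not verdicts:
                continue
            keep = [v for v in verdicts if v.verdict != "excluded"]
            result.entries.append(
                EndpointResult(
                    scope=scope,
                    module_id=module_id,
                    endpoint_id=endpoint_id,
                    ranked=rank_assays(kb, keep),
                    excluded=[v for v in verdicts if v.verdict == "excluded"],
                )
            )
    return result
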