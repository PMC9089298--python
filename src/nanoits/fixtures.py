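"""Packaged knowledge base and case-study dossiers, plus random generators.

``default_kb()`` loads the shipped catalogue (particle-size, surface-charge,
polydispersity and refractive-index bins; the tracking-analysis, light-
scattering, fractionation and skin-sensitisation rules).  The four
case-study dossiers -- a dextran-coated iron-oxide medical device (``ionp``),
a PEGylated liposome (``liposome``), an iron-carbohydrate product
(``iron_carbohydrate``), a poly(alkylcyanoacrylate) product (``paca``) --
and the knowledge-free ``empty`` dossier carry the minimal asserted classes
that reproduce the published filtering outcomes.

The ``generate_random_*`` functions build seed-deterministic, always-valid
knowledge bases, rules, and dossiers for property tests.
"""

from __future__ import annotations

import random
from importlib import resources
from typing import List, Optional, Union

from .dossier import NHPDossier, create_nhp, loads_dossier
from .kb import (
    AssayDef,
    CharacteristicProfile,
    ClassDef,
    EndpointDef,
    Interval,
    KnowledgeBase,
    ModuleDef,
    loads_kb,
)
from .rules import Atom, FactState, RuleExpr

__all__ = [
    "DOSSIER_NAMES",
    "default_kb",
    "default_kb_path",
    "dossier_fixture",
    "generate_random_kb",
    "generate_random_rule",
    "generate_random_dossier",
    "random_fact_state",
]

DOSSIER_NAMES = ("empty", "ionp", "liposome", "iron_carbohydrate", "paca")

_DATA = resources.files("nanoits") / "data"


def default_kb_path() -> str:
    """Filesystem path of the packaged knowledge-base file."""
    return str(_DATA / "default_kb.yaml")


def default_kb() -> KnowledgeBase:
    """Load the packaged knowledge base."""
    return loads_kb((_DATA / "default_kb.yaml").read_text(encoding="utf-8"),
                    source="default_kb.yaml")


def dossier_fixture(name: str) -> NHPDossier:
    """Load one of the packaged case-study dossiers by name."""
    if name not in DOSSIER_NAMES:
        raise KeyError(f"unknown dossier fixture {name!r} (choose from {DOSSIER_NAMES})")
    text = (_DATA / "dossiers" / f"{name}.yaml").read_text(encoding="utf-8")
    return loads_dossier(text, source=f"{name}.yaml")


# ---------------------------------------------------------------------------
# random generators (deterministic per seed)
# ---------------------------------------------------------------------------


def _random_quantitative(rng: random.Random, eid: str, module_id: str) -> EndpointDef:
    width = rng.choice([1.0, 10.0, 100.0, 1000.0])
    n_bins = rng.randint(2, 4)
    cuts = sorted(rng.sample([round(width * k / 20, 6) for k in range(1, 20)], n_bins - 1))
    classes = []
    bounds = [None] + cuts + [None]
    for i in range(n_bins):
        classes.append(ClassDef(label=f"c{i}", lower=bounds[i], upper=bounds[i + 1]))
    return EndpointDef(
        id=eid,
        module_id=module_id,
        label=eid,
        kind="quantitative",
        unit=rng.choice(["nm", "mV", ""]),
        classes=tuple(classes),
        domain=Interval(0.0, width, True, True),
    )


def _random_qualitative(rng: random.Random, eid: str, module_id: str) -> EndpointDef:
    n = rng.randint(2, 4)
    return EndpointDef(
        id=eid,
        module_id=module_id,
        label=eid,
        kind="qualitative",
        classes=tuple(ClassDef(label=f"q{i}") for i in range(n)),
    )


def generate_random_rule(
    rng_or_seed: Union[int, random.Random],
    kb: KnowledgeBase,
    max_depth: int = 4,
    endpoints: Optional[List[str]] = None,
) -> RuleExpr:
    """A random well-formed, constant-free rule over the KB's endpoints."""
    rng = (
        random.Random(rng_or_seed) if isinstance(rng_or_seed, int) else rng_or_seed
    )
    pool = endpoints or [e.id for e in kb.endpoints]
    if not pool:
        raise ValueError("cannot build a rule over an endpoint-free KB")

    def atom() -> RuleExpr:
        endpoint = kb.get_endpoint(rng.choice(pool))
        labels = endpoint.class_labels()
        forms = ["class_is", "class_in"]
        if endpoint.kind == "quantitative":
            forms.append("range_within")
        form = rng.choice(forms)
        if form == "class_is":
            return RuleExpr.of(Atom("class_is", endpoint.id, rng.choice(labels)))
        if form == "class_in":
            k = rng.randint(1, len(labels))
            return RuleExpr.of(Atom("class_in", endpoint.id, frozenset(rng.sample(labels, k))))
        dom = endpoint.domain
        a, b = sorted(rng.uniform(dom.lower, dom.upper) for _ in range(2))
        return RuleExpr.of(Atom("range_within", endpoint.id, (round(a, 6), round(b, 6))))

    def build(depth: int) -> RuleExpr:
        if depth <= 0 or rng.random() < 0.35:
            return atom()
        kind = rng.choice(["and", "or", "not"])
        if kind == "not":
            return RuleExpr.negate(build(depth - 1))
        children = tuple(build(depth - 1) for _ in range(rng.randint(2, 3)))
        return RuleExpr(and_=children) if kind == "and" else RuleExpr(or_=children)

    return build(max_depth)


def generate_random_kb(
    seed: int,
    n_endpoints: int = 6,
    n_assays: int = 8,
    max_rule_depth: int = 3,
) -> KnowledgeBase:
    """A seed-deterministic KB that always passes validation."""
    if max_rule_depth > 6:
        raise ValueError("max_rule_depth must be <= 6")
    rng = random.Random(seed)
    module = ModuleDef(id="module_0", label="Random module")
    endpoints = []
    for i in range(n_endpoints):
        maker = _random_quantitative if rng.random() < 0.5 else _random_qualitative
        endpoints.append(maker(rng, f"e{i}", module.id))
    kb = KnowledgeBase(modules=(module,), endpoints=tuple(endpoints))
    assays = []
    for i in range(n_assays):
        measures = tuple(
            sorted(rng.sample([e.id for e in endpoints], rng.randint(1, min(2, n_endpoints))))
        )
        rule = (
            generate_random_rule(rng, kb, max_rule_depth)
            if endpoints and rng.random() < 0.8
            else None
        )
        assays.append(
            AssayDef(
                id=f"a{i}",
                name=f"Random assay {i}",
                module_id=module.id,
                measures=measures,
                characteristics=CharacteristicProfile(
                    *(rng.choice(["low", "medium", "high"]) for _ in range(4))
                ),
                applicability=rule,
            )
        )
    return KnowledgeBase(
        modules=(module,), endpoints=tuple(endpoints), assays=tuple(assays)
    )


def generate_random_dossier(
    seed: int, kb: KnowledgeBase, completeness: float = 0.5
) -> NHPDossier:
    """A dossier assigning each endpoint a random class with P = completeness."""
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must be in [0, 1]")
    rng = random.Random(seed)
    dossier = create_nhp(
        f"random-{seed}",
        "medicinal_product",
        {"clinical_indication": "other", "administration_route": "intravenous"},
    )
    facts = dossier.scope_facts()
    for endpoint in kb.endpoints:
        if rng.random() < completeness:
            label = rng.choice(endpoint.class_labels())
            facts.assign(endpoint.id, label)
            if endpoint.kind == "quantitative":
                # a raw value inside the asserted bin, so range atoms
                # resolve definitely once the endpoint is known
                iv = endpoint.class_interval(label)
                facts.values[endpoint.id] = round(
                    iv.lower + (iv.upper - iv.lower) * rng.uniform(0.25, 0.75), 6
                )
    return dossier


def random_fact_state(
    rng_or_seed: Union[int, random.Random],
    kb: KnowledgeBase,
    completeness: float = 0.5,
) -> FactState:
    """Bare fact state over the KB's endpoints (rule-engine property tests)."""
    rng = (
        random.Random(rng_or_seed) if isinstance(rng_or_seed, int) else rng_or_seed
    )
    facts = FactState()
    for endpoint in kb.endpoints:
        if rng.random() < completeness:
            facts.assign(endpoint.id, rng.choice(endpoint.class_labels()))
    return facts
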