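"""Nano-enabled health product (NHP) dossier: the dynamic half of the system.

A dossier records what is currently known about one product: its header
(medical device vs medicinal product and the type-specific descriptors),
the components of the embedded nanomaterial and their layers, the asserted
classification/characterization classes (a :class:`~nanoits.rules.FactState`
for the whole nanomaterial and one per component), and the raw measurement
records.  Measurements never mutate the fact state on their own; classes are
asserted either directly (:func:`set_classification`) or derived from the
records by an explicit :func:`derive_characterization` call, so the testing
strategy is always driven by deliberately asserted knowledge.
"""

from __future__ import annotations

import os
import re
import statistics
import tempfile
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple, Union

import yaml

from .kb import KnowledgeBase, KBError, Violation, classify_value
from .rules import FactState

__all__ = [
    "NHPDossier",
    "Component",
    "MeasurementRecord",
    "DossierError",
    "WHOLE_NM",
    "MD_CATEGORIES",
    "MP_CATEGORIES",
    "create_nhp",
    "add_component",
    "set_classification",
    "add_measurement",
    "derive_characterization",
    "validate_dossier",
    "load_dossier",
    "save_dossier",
    "loads_dossier",
    "dumps_dossier",
]

WHOLE_NM = "nm"  # scope key for whole-nanomaterial facts

MP_CATEGORIES = ("api", "excipient", "buffer", "impurity")
MD_CATEGORIES = ("generic",)
LAYERS = ("core", "shell", "coating")

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


class DossierError(ValueError):
    """Invalid dossier content or mutation."""


@dataclass(frozen=True)
class Component:
    """One constituent of the nanomaterial, appointed to one or more layers."""

    name: str
    category: str
    layers: Tuple[str, ...]
    concentration: Optional[float] = None
    concentration_unit: str = ""
    cas_number: str = ""

    def __post_init__(self) -> None:
        if not self.layers:
            raise DossierError(f"component {self.name!r} needs at least one layer")
        for layer in self.layers:
            if layer not in LAYERS:
                raise DossierError(f"unknown layer {layer!r} (expected one of {LAYERS})")
        if self.cas_number and not _CAS_RE.match(self.cas_number):
            raise DossierError(f"malformed CAS number {self.cas_number!r}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw assay result with its experimental context."""

    assay_id: str
    endpoint_id: str
    value: float
    unit: str
    conditions: str = ""
    media: str = ""
    replicate: int = 1
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise DossierError("replicate index must be a positive integer")


@dataclass
class NHPDossier:
    name: str
    product_type: str  # "medical_device" | "medicinal_product"
    description: str = ""
    md_props: Optional[Dict[str, str]] = None  # device_category/contact_type/contact_duration
    mp_props: Optional[Dict[str, str]] = None  # clinical_indication/administration_route
    components: List[Component] = field(default_factory=list)
    facts: Dict[str, FactState] = field(default_factory=dict)  # scope -> facts
    measurements: Dict[str, List[MeasurementRecord]] = field(default_factory=dict)
    provenance: Dict[str, Dict[str, dict]] = field(default_factory=dict)

    def scope_facts(self, scope: str = WHOLE_NM) -> FactState:
        if scope not in self.facts:
            self.facts[scope] = FactState()
        return self.facts[scope]

    def scopes(self) -> List[str]:
        return [WHOLE_NM] + [c.name for c in self.components]

    def product_facts(self) -> FactState:
        """Product-header descriptors exposed as endpoint facts.

        The header fields (administration route, contact type, ...) feed the
        same rule engine as nanomaterial classes, so module/endpoint scoping
        rules and assay rules share one vocabulary.
        """
        facts = FactState()
        props = self.md_props if self.product_type == "medical_device" else self.mp_props
        mapping = {
            "device_category": "device_category",
            "contact_type": "contact_type",
            "contact_duration": "contact_duration",
            "clinical_indication": "clinical_indication",
            "administration_route": "route_of_administration",
            "dermal_systemic_exposure": "dermal_systemic_exposure",
        }
        for key, endpoint_id in mapping.items():
            value = (props or {}).get(key)
            if value:
                facts.assign(endpoint_id, value)
        return facts

    def effective_facts(self, scope: str = WHOLE_NM) -> FactState:
        """Product-level facts overlaid with the scope's asserted classes."""
        return self.product_facts().merged(self.scope_facts(scope))


# ---------------------------------------------------------------------------
# lifecycle operations (functional style: return the mutated dossier)
# ---------------------------------------------------------------------------

_MD_REQUIRED = ("device_category", "contact_type", "contact_duration")
_MP_REQUIRED = ("clinical_indication", "administration_route")


def create_nhp(
    name: str,
    product_type: str,
    props: Mapping[str, str],
    description: str = "",
) -> NHPDossier:
    """Create a dossier with empty components and fact states."""
    if product_type == "medical_device":
        required = _MD_REQUIRED
    elif product_type == "medicinal_product":
        required = _MP_REQUIRED
    else:
        raise DossierError(f"unknown product type {product_type!r}")
    missing = [k for k in required if not props.get(k)]
    if missing:
        raise DossierError(f"{product_type} requires {', '.join(missing)}")
    clean = {k: v for k, v in props.items() if v}
    return NHPDossier(
        name=name,
        product_type=product_type,
        description=description,
        md_props=clean if product_type == "medical_device" else None,
        mp_props=clean if product_type == "medicinal_product" else None,
    )


def add_component(dossier: NHPDossier, component: Component) -> NHPDossier:
    legal = MD_CATEGORIES if dossier.product_type == "medical_device" else MP_CATEGORIES
    if component.category not in legal:
        raise DossierError(
            f"category {component.category!r} is not legal for a "
            f"{dossier.product_type} (expected one of {legal})"
        )
    if any(c.name == component.name for c in dossier.components):
        raise DossierError(f"duplicate component name {component.name!r}")
    dossier.components.append(component)
    dossier.facts.setdefault(component.name, FactState())
    return dossier


def set_classification(
    dossier: NHPDossier,
    kb: KnowledgeBase,
    scope: str,
    endpoint_id: str,
    class_label: str,
    replace_existing: bool = False,
) -> NHPDossier:
    """Assert a qualitative class, honouring the classification tree's
    single-choice consistency rule (no silent re-selection of a sibling)."""
    endpoint = kb.get_endpoint(endpoint_id)
    if class_label not in endpoint.class_labels():
        raise DossierError(
            f"endpoint {endpoint_id!r} has no class {class_label!r} "
            f"(choices: {endpoint.class_labels()})"
        )
    if scope != WHOLE_NM and all(c.name != scope for c in dossier.components):
        raise DossierError(f"unknown scope {scope!r}")
    facts = dossier.scope_facts(scope)
    current = facts.classes.get(endpoint_id)
    if endpoint.selection_mode == "single_choice":
        if current is not None and class_label not in current and not replace_existing:
            raise DossierError(
                f"endpoint {endpoint_id!r} already set to {sorted(current)}; "
                f"selecting {class_label!r} too would violate its single-choice "
                "branch (pass replace_existing=True to replace)"
            )
        facts.assign(endpoint_id, class_label)
    else:  # multi_choice accumulates; replace resets the selection
        selection = (
            frozenset([class_label])
            if replace_existing or current is None
            else current | {class_label}
        )
        facts.assign(endpoint_id, selection)
    return dossier


def add_measurement(
    dossier: NHPDossier,
    kb: KnowledgeBase,
    scope: str,
    record: MeasurementRecord,
) -> NHPDossier:
    """Append a raw result; fact states are deliberately left untouched."""
    kb.get_assay(record.assay_id)
    endpoint = kb.get_endpoint(record.endpoint_id)
    if record.unit != endpoint.unit:
        raise DossierError(
            f"unit {record.unit!r} does not match endpoint "
            f"{record.endpoint_id!r} unit {endpoint.unit!r}"
        )
    if scope != WHOLE_NM and all(c.name != scope for c in dossier.components):
        raise DossierError(f"unknown scope {scope!r}")
    dossier.measurements.setdefault(scope, []).append(record)
    return dossier


_AGGREGATORS = {
    "median": lambda values, records: statistics.median(values),
    "mean": lambda values, records: statistics.fmean(values),
    "latest": lambda values, records: max(
        zip(records, values), key=lambda rv: rv[0].timestamp
    )[1],
}


def derive_characterization(
    dossier: NHPDossier,
    kb: KnowledgeBase,
    scope: str,
    endpoint_id: str,
    aggregation: str = "median",
) -> NHPDossier:
    """Aggregate the endpoint's measurements, classify, and assert the class.

    Idempotent for unchanged records; provenance (records used, aggregate,
    statistic) is kept so a decision trace can cite its evidence.
    """
    if aggregation not in _AGGREGATORS:
        raise DossierError(f"unknown aggregation {aggregation!r}")
    records = [
        r for r in dossier.measurements.get(scope, []) if r.endpoint_id == endpoint_id
    ]
    if not records:
        raise DossierError(
            f"no measurements for endpoint {endpoint_id!r} in scope {scope!r}"
        )
    values = [r.value for r in records]
    aggregate = _AGGREGATORS[aggregation](values, records)
    label = classify_value(kb, endpoint_id, aggregate)  # KBError if out of domain
    facts = dossier.scope_facts(scope)
    facts.assign(endpoint_id, label)
    facts.values[endpoint_id] = float(aggregate)
    dossier.provenance.setdefault(scope, {})[endpoint_id] = {
        "aggregation": aggregation,
        "aggregate": float(aggregate),
        "class": label,
        "records": [
            {"assay_id": r.assay_id, "replicate": r.replicate, "timestamp": r.timestamp}
            for r in records
        ],
    }
    return dossier


# ---------------------------------------------------------------------------
# validation against a knowledge base
# ---------------------------------------------------------------------------


def validate_dossier(dossier: NHPDossier, kb: KnowledgeBase) -> list:
    """Cross-check the dossier's facts and records against the KB.

    Returns :class:`~nanoits.kb.Violation` records (empty when consistent):
    unknown endpoints/classes, numeric values outside an endpoint's domain
    or inconsistent with the asserted class, unit mismatches, and product
    header values that are not legal classes of their descriptor endpoint.
    """
    out = []

    def check_facts(entity: str, facts: FactState) -> None:
        for eid, labels in facts.classes.items():
            if not kb.has_endpoint(eid):
                out.append(Violation(entity, "dangling_reference", f"unknown endpoint {eid!r}"))
                continue
            endpoint = kb.get_endpoint(eid)
            for label in labels - set(endpoint.class_labels()):
                out.append(
                    Violation(entity, "unknown_class", f"endpoint {eid!r} has no class {label!r}")
                )
            if len(labels) > 1 and endpoint.selection_mode == "single_choice":
                out.append(
                    Violation(
                        entity, "single_choice_violation",
                        f"endpoint {eid!r} carries multiple classes {sorted(labels)}",
                    )
                )
        for eid, value in facts.values.items():
            if not kb.has_endpoint(eid):
                out.append(Violation(entity, "dangling_reference", f"unknown endpoint {eid!r}"))
                continue
            try:
                derived = classify_value(kb, eid, value)
            except KBError as exc:
                out.append(Violation(entity, "value_out_of_domain", str(exc)))
                continue
            asserted = facts.classes.get(eid)
            if asserted is not None and derived not in asserted:
                out.append(
                    Violation(
                        entity, "class_value_mismatch",
                        f"value {value} of {eid!r} falls in class {derived!r}, "
                        f"not the asserted {sorted(asserted)}",
                    )
                )

    for scope, facts in dossier.facts.items():
        if scope != WHOLE_NM and all(c.name != scope for c in dossier.components):
            out.append(Violation(f"facts:{scope}", "dangling_reference", f"unknown scope {scope!r}"))
        check_facts(f"facts:{scope}", facts)
    check_facts("product_header", dossier.product_facts())

    legal = MD_CATEGORIES if dossier.product_type == "medical_device" else MP_CATEGORIES
    for c in dossier.components:
        if c.category not in legal:
            out.append(
                Violation(
                    f"component:{c.name}", "illegal_category",
                    f"category {c.category!r} not legal for {dossier.product_type}",
                )
            )

    for scope, records in dossier.measurements.items():
        for r in records:
            entity = f"measurement:{scope}:{r.assay_id}:{r.endpoint_id}"
            try:
                kb.get_assay(r.assay_id)
            except KBError:
                out.append(Violation(entity, "dangling_reference", f"unknown assay {r.assay_id!r}"))
            if not kb.has_endpoint(r.endpoint_id):
                out.append(Violation(entity, "dangling_reference", f"unknown endpoint {r.endpoint_id!r}"))
            elif r.unit != kb.get_endpoint(r.endpoint_id).unit:
                out.append(
                    Violation(
                        entity, "unit_mismatch",
                        f"unit {r.unit!r} != endpoint unit {kb.get_endpoint(r.endpoint_id).unit!r}",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _facts_to_raw(facts: FactState) -> dict:
    out: dict = {}
    if facts.classes:
        out["classes"] = {
            eid: (sorted(labels)[0] if len(labels) == 1 else sorted(labels))
            for eid, labels in sorted(facts.classes.items())
        }
    if facts.values:
        out["values"] = {eid: facts.values[eid] for eid in sorted(facts.values)}
    return out


def _facts_from_raw(raw: Mapping) -> FactState:
    facts = FactState()
    for eid, label in (raw.get("classes") or {}).items():
        facts.assign(eid, label)
    facts.values = {eid: float(v) for eid, v in (raw.get("values") or {}).items()}
    return facts


def dumps_dossier(dossier: NHPDossier) -> str:
    raw: dict = {
        "schema_version": "1.0",
        "name": dossier.name,
        "description": dossier.description,
        "product_type": dossier.product_type,
    }
    if dossier.md_props is not None:
        raw["md_props"] = dict(dossier.md_props)
    if dossier.mp_props is not None:
        raw["mp_props"] = dict(dossier.mp_props)
    raw["components"] = [
        {
            "name": c.name,
            "category": c.category,
            "layers": list(c.layers),
            **({"concentration": c.concentration} if c.concentration is not None else {}),
            **({"concentration_unit": c.concentration_unit} if c.concentration_unit else {}),
            **({"cas_number": c.cas_number} if c.cas_number else {}),
        }
        for c in dossier.components
    ]
    raw["facts"] = {
        scope: _facts_to_raw(facts)
        for scope, facts in sorted(dossier.facts.items())
        if facts.classes or facts.values
    }
    raw["measurements"] = {
        scope: [
            {
                "assay_id": r.assay_id,
                "endpoint_id": r.endpoint_id,
                "value": r.value,
                "unit": r.unit,
                "conditions": r.conditions,
                "media": r.media,
                "replicate": r.replicate,
                "timestamp": r.timestamp,
            }
            for r in records
        ]
        for scope, records in sorted(dossier.measurements.items())
        if records
    }
    if dossier.provenance:
        raw["provenance"] = dossier.provenance
    return yaml.safe_dump(raw, sort_keys=False, default_flow_style=False)


def loads_dossier(text: str, source: str = "<string>") -> NHPDossier:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise DossierError(f"{source}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise DossierError(f"{source}: top level must be a mapping")
    try:
        dossier = NHPDossier(
            name=raw["name"],
            product_type=raw["product_type"],
            description=raw.get("description", ""),
            md_props=dict(raw["md_props"]) if raw.get("md_props") else None,
            mp_props=dict(raw["mp_props"]) if raw.get("mp_props") else None,
        )
    except KeyError as exc:
        raise DossierError(f"{source}: missing key {exc}") from None
    for c in raw.get("components", []):
        dossier.components.append(
            Component(
                name=c["name"],
                category=c["category"],
                layers=tuple(c["layers"]),
                concentration=c.get("concentration"),
                concentration_unit=c.get("concentration_unit", ""),
                cas_number=c.get("cas_number", ""),
            )
        )
    for scope, facts_raw in (raw.get("facts") or {}).items():
        dossier.facts[scope] = _facts_from_raw(facts_raw or {})
    for scope, records in (raw.get("measurements") or {}).items():
        dossier.measurements[scope] = [
            MeasurementRecord(
                assay_id=r["assay_id"],
                endpoint_id=r["endpoint_id"],
                value=float(r["value"]),
                unit=r.get("unit", ""),
                conditions=r.get("conditions", ""),
                media=r.get("media", ""),
                replicate=int(r.get("replicate", 1)),
                timestamp=r.get("timestamp", ""),
            )
            for r in records
        ]
    dossier.provenance = {
        scope: dict(entries) for scope, entries in (raw.get("provenance") or {}).items()
    }
    return dossier


def load_dossier(path: Union[str, os.PathLike]) -> NHPDossier:
    with open(path, "r", encoding="utf-8") as fh:
        return loads_dossier(fh.read(), source=str(path))


def save_dossier(dossier: NHPDossier, path: Union[str, os.PathLike]) -> None:
    """Atomic write: temp file in the target directory, then rename."""
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(prefix=".dossier-", suffix=".tmp", dir=directory)
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(dumps_dossier(dossier))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
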