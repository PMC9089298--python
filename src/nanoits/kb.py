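"""Declarative knowledge base: modules, category endpoints, class bins, assays.

The knowledge base is the static half of the decision system.  It declares,
per assessment module (physicochemical, immunotoxicity, ...), the category
endpoints of the nanomaterial (particle size diameter, surface charge,
polydispersity, ...), a partition of each quantitative endpoint's domain
into qualitative class bins (e.g. surface charge: negative / neutral /
positive around +/-10 mV), and the catalogue of assays with their
four ordinal characteristics (duration, cost, resolution, expertise) and an
optional applicability rule.

Files are YAML (JSON is a YAML subset and is accepted unchanged); the
authoritative shape is documented in ``schemas/kb.schema.json``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .rules import RuleExpr, rule_from_dict, rule_to_dict, atoms_of

__all__ = [
    "Interval",
    "ClassDef",
    "EndpointDef",
    "CharacteristicProfile",
    "AssayDef",
    "ModuleDef",
    "SelectionRule",
    "KnowledgeBase",
    "Violation",
    "KBError",
    "SchemaError",
    "ReferenceError_",
    "load_kb",
    "loads_kb",
    "write_kb",
    "dumps_kb",
    "validate_kb",
    "classify_value",
    "characteristic_score",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

CHARACTERISTIC_SCORES = {"low": 1, "medium": 2, "high": 3}
PRODUCT_TYPES = ("medical_device", "medicinal_product")


class KBError(ValueError):
    """Base error for knowledge-base problems."""


class SchemaError(KBError):
    """File does not match the documented KB schema."""


class ReferenceError_(KBError):
    """A cross-reference (endpoint/assay/module id) does not resolve."""


@dataclass(frozen=True)
class Violation:
    """One broken invariant; validation returns these as data."""

    entity: str  # e.g. "endpoint:particle_size_lower"
    invariant: str  # short machine-ish tag, e.g. "coverage_gap"
    message: str

    def __str__(self) -> str:
        return f"{self.entity}: {self.invariant}: {self.message}"


# ---------------------------------------------------------------------------
# intervals / class bins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """A real interval with per-side inclusivity."""

    lower: float
    upper: float
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    def contains(self, v: float) -> bool:
        above = v > self.lower or (v == self.lower and self.lower_inclusive)
        below = v < self.upper or (v == self.upper and self.upper_inclusive)
        return above and below

    def subset_of(self, lo: float, hi: float) -> bool:
        """Is this interval contained in the *closed* range [lo, hi]?"""
        return self.lower >= lo and self.upper <= hi

    def disjoint_from(self, lo: float, hi: float) -> bool:
        """Does this interval miss the closed range [lo, hi] entirely?"""
        if self.upper < lo or (self.upper == lo and not self.upper_inclusive):
            return True
        if self.lower > hi or (self.lower == hi and not self.lower_inclusive):
            return True
        return False


@dataclass(frozen=True)
class ClassDef:
    """One qualitative class; bounds only for quantitative endpoints.

    A missing bound means "up to the endpoint domain's edge".  Bins are
    left-closed/right-open by default ([lo, hi)); the inclusivity flags
    allow overrides such as the neutral surface-charge class owning both
    of its +/-10 mV boundaries.
    """

    label: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    lower_inclusive: bool = True
    upper_inclusive: bool = False


@dataclass(frozen=True)
class EndpointDef:
    id: str
    module_id: str
    label: str
    kind: str  # "qualitative" | "quantitative"
    unit: str = ""
    classes: Tuple[ClassDef, ...] = ()
    domain: Optional[Interval] = None  # quantitative only
    selection_mode: str = "single_choice"  # classification-tree branch mode

    def class_labels(self) -> List[str]:
        return [c.label for c in self.classes]

    def get_class(self, label: str) -> ClassDef:
        for c in self.classes:
            if c.label == label:
                return c
        raise KBError(f"endpoint {self.id!r} has no class {label!r}")

    def class_interval(self, label: str) -> Interval:
        """Resolve a class bin to a concrete interval (None bounds -> domain)."""
        if self.kind != "quantitative" or self.domain is None:
            raise KBError(f"endpoint {self.id!r} is not quantitative")
        c = self.get_class(label)
        lower = self.domain.lower if c.lower is None else c.lower
        upper = self.domain.upper if c.upper is None else c.upper
        lower_inc = self.domain.lower_inclusive if c.lower is None else c.lower_inclusive
        upper_inc = self.domain.upper_inclusive if c.upper is None else c.upper_inclusive
        return Interval(lower, upper, lower_inc, upper_inc)


@dataclass(frozen=True)
class CharacteristicProfile:
    """The four ordinal assay characteristics on the low/medium/high scale."""

    duration: str
    cost: str
    resolution: str
    expertise: str

    def __post_init__(self) -> None:
        for name in ("duration", "cost", "resolution", "expertise"):
            if getattr(self, name) not in CHARACTERISTIC_SCORES:
                raise KBError(
                    f"characteristic {name} must be low/medium/high, "
                    f"got {getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class AssayDef:
    id: str
    name: str
    module_id: str
    measures: Tuple[str, ...]
    characteristics: CharacteristicProfile
    applicability: Optional[RuleExpr] = None  # None => always applicable
    user_defined: bool = False


@dataclass(frozen=True)
class ModuleDef:
    id: str
    label: str
    product_scope: Tuple[str, ...] = PRODUCT_TYPES


@dataclass(frozen=True)
class SelectionRule:
    """Scopes a module or endpoint by a rule over product-level facts."""

    target_id: str  # module id or endpoint id
    rule: RuleExpr


@dataclass(frozen=True)
class KnowledgeBase:
    schema_version: str = SCHEMA_VERSION
    modules: Tuple[ModuleDef, ...] = ()
    endpoints: Tuple[EndpointDef, ...] = ()
    assays: Tuple[AssayDef, ...] = ()
    module_selection_rules: Tuple[SelectionRule, ...] = ()
    _endpoint_index: Dict[str, EndpointDef] = field(
        default_factory=dict, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_endpoint_index", {e.id: e for e in self.endpoints}
        )

    def get_endpoint(self, endpoint_id: str) -> EndpointDef:
        try:
            return self._endpoint_index[endpoint_id]
        except KeyError:
            raise ReferenceError_(f"unknown endpoint {endpoint_id!r}") from None

    def has_endpoint(self, endpoint_id: str) -> bool:
        return endpoint_id in self._endpoint_index

    def get_assay(self, assay_id: str) -> AssayDef:
        for a in self.assays:
            if a.id == assay_id:
                return a
        raise ReferenceError_(f"unknown assay {assay_id!r}")

    def get_module(self, module_id: str) -> ModuleDef:
        for m in self.modules:
            if m.id == module_id:
                return m
        raise ReferenceError_(f"unknown module {module_id!r}")

    def assays_measuring(self, endpoint_id: str) -> List[AssayDef]:
        return [a for a in self.assays if endpoint_id in a.measures]

    def with_assay(self, assay: AssayDef) -> "KnowledgeBase":
        return replace(self, assays=self.assays + (assay,))


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def classify_value(kb: KnowledgeBase, endpoint_id: str, value: float) -> str:
    """Map a raw measurement to the unique class bin containing it."""
    endpoint = kb.get_endpoint(endpoint_id)
    if endpoint.kind != "quantitative":
        raise KBError(f"endpoint {endpoint_id!r} is qualitative")
    if endpoint.domain is None or not endpoint.domain.contains(value):
        raise KBError(
            f"value {value} outside the domain of endpoint {endpoint_id!r}"
        )
    for c in endpoint.classes:
        if endpoint.class_interval(c.label).contains(value):
            return c.label
    raise KBError(  # unreachable on a valid (gap-free) KB
        f"no class bin of {endpoint_id!r} contains {value}"
    )


def characteristic_score(class_label: str) -> int:
    """Ordinal score of a characteristic class: low -> 1, medium -> 2, high -> 3."""
    try:
        return CHARACTERISTIC_SCORES[class_label]
    except KeyError:
        raise KBError(f"unknown characteristic class {class_label!r}") from None


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_duplicates(items: Sequence[str], namespace: str, out: List[Violation]):
    seen: Dict[str, int] = {}
    for item in items:
        seen[item] = seen.get(item, 0) + 1
    for item, n in seen.items():
        if n > 1:
            out.append(
                Violation(
                    f"{namespace}:{item}",
                    "duplicate_id",
                    f"id {item!r} appears {n} times in {namespace}",
                )
            )


def _validate_quantitative_bins(e: EndpointDef, out: List[Violation]) -> None:
    entity = f"endpoint:{e.id}"
    if e.domain is None:
        out.append(Violation(entity, "missing_domain", "quantitative endpoint has no domain"))
        return
    if not e.classes:
        out.append(Violation(entity, "no_classes", "quantitative endpoint has no class bins"))
        return
    try:
        intervals = [e.class_interval(c.label) for c in e.classes]
    except KBError as exc:
        out.append(Violation(entity, "bad_bin", str(exc)))
        return
    for c, iv in zip(e.classes, intervals):
        if iv.lower > iv.upper or (
            iv.lower == iv.upper and not (iv.lower_inclusive and iv.upper_inclusive)
        ):
            out.append(
                Violation(entity, "empty_bin", f"class {c.label!r} has an empty interval")
            )
            return
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].lower, intervals[i].upper))
    ordered = [intervals[i] for i in order]
    labels = [e.classes[i].label for i in order]
    dom = e.domain
    if ordered[0].lower != dom.lower or ordered[0].lower_inclusive != dom.lower_inclusive:
        out.append(
            Violation(entity, "coverage_gap", f"domain start {dom.lower} not covered (first bin {labels[0]!r})")
        )
    if ordered[-1].upper != dom.upper or ordered[-1].upper_inclusive != dom.upper_inclusive:
        out.append(
            Violation(entity, "coverage_gap", f"domain end {dom.upper} not covered (last bin {labels[-1]!r})")
        )
    for (a, la), (b, lb) in zip(zip(ordered, labels), zip(ordered[1:], labels[1:])):
        if a.upper < b.lower:
            out.append(
                Violation(entity, "coverage_gap", f"gap [{a.upper}, {b.lower}) between {la!r} and {lb!r}")
            )
        elif a.upper > b.lower:
            out.append(
                Violation(entity, "overlap", f"classes {la!r} and {lb!r} overlap near {b.lower}")
            )
        else:  # shared boundary: exactly one side must own it
            if a.upper_inclusive == b.lower_inclusive:
                tag = "overlap" if a.upper_inclusive else "coverage_gap"
                out.append(
                    Violation(
                        entity, tag,
                        f"boundary {a.upper} between {la!r} and {lb!r} is "
                        + ("claimed by both" if a.upper_inclusive else "claimed by neither"),
                    )
                )


def _validate_rule_refs(rule: RuleExpr, kb: KnowledgeBase, entity: str, out: List[Violation]):
    for atom in atoms_of(rule):
        if not kb.has_endpoint(atom.endpoint_id):
            out.append(
                Violation(entity, "dangling_reference", f"rule references unknown endpoint {atom.endpoint_id!r}")
            )
        elif atom.form in ("class_is", "class_in"):
            endpoint = kb.get_endpoint(atom.endpoint_id)
            wanted = {atom.payload} if atom.form == "class_is" else atom.payload
            for label in wanted - set(endpoint.class_labels()):
                out.append(
                    Violation(entity, "dangling_reference", f"rule references unknown class {label!r} of endpoint {atom.endpoint_id!r}")
                )


def validate_kb(kb: KnowledgeBase) -> List[Violation]:
    """Check every structural invariant; returns violations as data."""
    out: List[Violation] = []
    _check_duplicates([m.id for m in kb.modules], "module", out)
    _check_duplicates([e.id for e in kb.endpoints], "endpoint", out)
    _check_duplicates([a.id for a in kb.assays], "assay", out)

    module_ids = {m.id for m in kb.modules}
    for m in kb.modules:
        for scope in m.product_scope:
            if scope not in PRODUCT_TYPES:
                out.append(Violation(f"module:{m.id}", "bad_product_scope", f"unknown product type {scope!r}"))

    for e in kb.endpoints:
        entity = f"endpoint:{e.id}"
        if e.module_id not in module_ids:
            out.append(Violation(entity, "dangling_reference", f"unknown module {e.module_id!r}"))
        if e.kind == "quantitative":
            _validate_quantitative_bins(e, out)
        elif e.kind == "qualitative":
            labels = e.class_labels()
            if len(labels) < 2:
                out.append(Violation(entity, "too_few_classes", "qualitative endpoint needs >= 2 classes"))
            if len(set(labels)) != len(labels):
                out.append(Violation(entity, "duplicate_class", "class labels not unique"))
        else:
            out.append(Violation(entity, "bad_kind", f"kind must be qualitative/quantitative, got {e.kind!r}"))
        if e.selection_mode not in ("single_choice", "multi_choice"):
            out.append(Violation(entity, "bad_selection_mode", f"got {e.selection_mode!r}"))

    for a in kb.assays:
        entity = f"assay:{a.id}"
        if a.module_id not in module_ids:
            out.append(Violation(entity, "dangling_reference", f"unknown module {a.module_id!r}"))
        if not a.measures:
            out.append(Violation(entity, "empty_measures", "assay measures no endpoint"))
        for eid in a.measures:
            if not kb.has_endpoint(eid):
                out.append(Violation(entity, "dangling_reference", f"measures unknown endpoint {eid!r}"))
        if a.applicability is not None:
            _validate_rule_refs(a.applicability, kb, entity, out)

    for sr in kb.module_selection_rules:
        entity = f"selection_rule:{sr.target_id}"
        if sr.target_id not in module_ids and not kb.has_endpoint(sr.target_id):
            out.append(Violation(entity, "dangling_reference", f"target {sr.target_id!r} is neither a module nor an endpoint"))
        _validate_rule_refs(sr.rule, kb, entity, out)

    return out


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------


def _interval_from_dict(d: Mapping, default=Interval(0.0, 0.0)) -> Interval:
    return Interval(
        float(d["lower"]),
        float(d["upper"]),
        bool(d.get("lower_inclusive", True)),
        bool(d.get("upper_inclusive", False)),
    )


def _class_from_dict(d: Mapping) -> ClassDef:
    if isinstance(d, str):  # qualitative shorthand: plain label
        return ClassDef(label=d)
    return ClassDef(
        label=d["label"],
        lower=None if d.get("lower") is None else float(d["lower"]),
        upper=None if d.get("upper") is None else float(d["upper"]),
        lower_inclusive=bool(d.get("lower_inclusive", True)),
        upper_inclusive=bool(d.get("upper_inclusive", False)),
    )


def _endpoint_from_dict(d: Mapping) -> EndpointDef:
    try:
        return EndpointDef(
            id=d["id"],
            module_id=d["module"],
            label=d.get("label", d["id"]),
            kind=d["kind"],
            unit=d.get("unit", ""),
            classes=tuple(_class_from_dict(c) for c in d.get("classes", [])),
            domain=None if d.get("domain") is None else _interval_from_dict(d["domain"]),
            selection_mode=d.get("selection_mode", "single_choice"),
        )
    except KeyError as exc:
        raise SchemaError(f"endpoint entry missing key {exc} in {d!r}") from None


def _assay_from_dict(d: Mapping) -> AssayDef:
    try:
        ch = d["characteristics"]
        return AssayDef(
            id=d["id"],
            name=d.get("name", d["id"]),
            module_id=d["module"],
            measures=tuple(d["measures"]),
            characteristics=CharacteristicProfile(
                duration=ch["duration"], cost=ch["cost"],
                resolution=ch["resolution"], expertise=ch["expertise"],
            ),
            applicability=None if d.get("applicability") is None else rule_from_dict(d["applicability"]),
            user_defined=bool(d.get("user_defined", False)),
        )
    except KeyError as exc:
        raise SchemaError(f"assay entry missing key {exc} in {d!r}") from None


def loads_kb(text: str, source: str = "<string>") -> KnowledgeBase:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise SchemaError(f"{source}: not valid YAML/JSON{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{source}: top level must be a mapping")
    version = str(raw.get("schema_version", SCHEMA_VERSION))
    if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(f"{source}: unsupported schema_version {version!r}")
    try:
        kb = KnowledgeBase(
            schema_version=version,
            modules=tuple(
                ModuleDef(
                    id=m["id"],
                    label=m.get("label", m["id"]),
                    product_scope=tuple(m.get("product_scope", PRODUCT_TYPES)),
                )
                for m in raw.get("modules", [])
            ),
            endpoints=tuple(_endpoint_from_dict(e) for e in raw.get("endpoints", [])),
            assays=tuple(_assay_from_dict(a) for a in raw.get("assays", [])),
            module_selection_rules=tuple(
                SelectionRule(target_id=r["target"], rule=rule_from_dict(r["rule"]))
                for r in raw.get("module_selection_rules", [])
            ),
        )
    except KeyError as exc:
        raise SchemaError(f"{source}: entry missing key {exc}") from None
    dangling = [v for v in validate_kb(kb) if v.invariant == "dangling_reference"]
    if dangling:
        raise ReferenceError_(
            f"{source}: unresolved references: " + "; ".join(str(v) for v in dangling)
        )
    return kb


def load_kb(path: Union[str, os.PathLike]) -> KnowledgeBase:
    """Load and cross-link a knowledge base from a YAML/JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_kb(fh.read(), source=str(path))


def _class_to_dict(c: ClassDef, quantitative: bool):
    if not quantitative:
        return c.label
    d: dict = {"label": c.label}
    if c.lower is not None:
        d["lower"] = c.lower
    if c.upper is not None:
        d["upper"] = c.upper
    if not c.lower_inclusive:
        d["lower_inclusive"] = False
    if c.upper_inclusive:
        d["upper_inclusive"] = True
    return d


def _kb_to_raw(kb: KnowledgeBase) -> dict:
    return {
        "schema_version": kb.schema_version,
        "modules": [
            {"id": m.id, "label": m.label, "product_scope": list(m.product_scope)}
            for m in kb.modules
        ],
        "endpoints": [
            {
                "id": e.id,
                "module": e.module_id,
                "label": e.label,
                "kind": e.kind,
                **({"unit": e.unit} if e.unit else {}),
                **(
                    {
                        "domain": {
                            "lower": e.domain.lower,
                            "upper": e.domain.upper,
                            "lower_inclusive": e.domain.lower_inclusive,
                            "upper_inclusive": e.domain.upper_inclusive,
                        }
                    }
                    if e.domain is not None
                    else {}
                ),
                "classes": [_class_to_dict(c, e.kind == "quantitative") for c in e.classes],
                **(
                    {"selection_mode": e.selection_mode}
                    if e.selection_mode != "single_choice"
                    else {}
                ),
            }
            for e in kb.endpoints
        ],
        "assays": [
            {
                "id": a.id,
                "name": a.name,
                "module": a.module_id,
                "measures": list(a.measures),
                "characteristics": {
                    "duration": a.characteristics.duration,
                    "cost": a.characteristics.cost,
                    "resolution": a.characteristics.resolution,
                    "expertise": a.characteristics.expertise,
                },
                **(
                    {"applicability": rule_to_dict(a.applicability)}
                    if a.applicability is not None
                    else {}
                ),
                **({"user_defined": True} if a.user_defined else {}),
            }
            for a in kb.assays
        ],
        "module_selection_rules": [
            {"target": r.target_id, "rule": rule_to_dict(r.rule)}
            for r in kb.module_selection_rules
        ],
    }


def dumps_kb(kb: KnowledgeBase) -> str:
    buf = io.StringIO()
    yaml.safe_dump(_kb_to_raw(kb), buf, sort_keys=False, default_flow_style=False)
    return buf.getvalue()


def write_kb(kb: KnowledgeBase, path: Union[str, os.PathLike]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_kb(kb))
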