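"""Three-valued rule engine over endpoint-class atoms.

Applicability rules are finite AND/OR/NOT trees whose leaves (atoms) test
the qualitative class, class membership, or measurable range of a single
category endpoint.  Because a dossier is almost always incomplete, rules
are evaluated under Kleene's strong three-valued logic: an unassigned
endpoint yields UNKNOWN, and UNKNOWN propagates through the connectives
(AND = min, OR = max over the order FALSE < UNKNOWN < TRUE).  Missing
knowledge therefore never produces a definite verdict, which is what lets
the testing-strategy layer keep an assay on the table until it is *known*
to be unsuitable.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Union

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .kb import KnowledgeBase

__all__ = [
    "TruthValue",
    "Atom",
    "RuleExpr",
    "FactState",
    "RuleError",
    "eval_atom",
    "eval_rule",
    "eval_rule_oracle",
    "explain",
    "TraceNode",
    "false_atoms",
    "rule_from_dict",
    "rule_to_dict",
    "atoms_of",
    "endpoints_of",
]


class RuleError(ValueError):
    """Malformed rule expression or unresolvable atom."""


class TruthValue(enum.IntEnum):
    """Kleene truth value; the integer order FALSE < UNKNOWN < TRUE makes
    conjunction ``min`` and disjunction ``max``."""

    FALSE = 0
    UNKNOWN = 1
    TRUE = 2

    def __invert__(self) -> "TruthValue":
        if self is TruthValue.TRUE:
            return TruthValue.FALSE
        if self is TruthValue.FALSE:
            return TruthValue.TRUE
        return TruthValue.UNKNOWN


@dataclass(frozen=True)
class Atom:
    """A leaf test on one endpoint.

    form
        ``class_is``     -- the assigned class equals ``payload`` (a label)
        ``class_in``     -- the assigned class is one of ``payload`` (a set)
        ``range_within`` -- the endpoint's value/class bin lies inside the
                            closed interval ``payload`` = (lower, upper)
    """

    form: str
    endpoint_id: str
    payload: Union[str, frozenset, tuple]

    def __post_init__(self) -> None:
        if self.form not in ("class_is", "class_in", "range_within"):
            raise RuleError(f"unknown atom form {self.form!r}")
        if self.form == "class_in":
            object.__setattr__(self, "payload", frozenset(self.payload))
            if not self.payload:
                raise RuleError("class_in payload must be non-empty")
        if self.form == "range_within":
            lo, hi = self.payload
            if lo > hi:
                raise RuleError(f"range_within lower {lo} > upper {hi}")
            object.__setattr__(self, "payload", (float(lo), float(hi)))


@dataclass(frozen=True)
class RuleExpr:
    """Node of a rule tree: exactly one of atom / and_ / or_ / not_ set."""

    atom: Optional[Atom] = None
    and_: Optional[tuple] = None
    or_: Optional[tuple] = None
    not_: Optional["RuleExpr"] = None

    def __post_init__(self) -> None:
        set_fields = [
            f for f in (self.atom, self.and_, self.or_, self.not_) if f is not None
        ]
        if len(set_fields) != 1:
            raise RuleError("RuleExpr must have exactly one of atom/and/or/not")
        for children in (self.and_, self.or_):
            if children is not None:
                object.__setattr__(
                    self, "and_" if children is self.and_ else "or_", tuple(children)
                )
                if len(children) < 2:
                    raise RuleError("and/or need at least 2 children")

    # -- convenience constructors -------------------------------------
    @staticmethod
    def of(atom: Atom) -> "RuleExpr":
        return RuleExpr(atom=atom)

    @staticmethod
    def all(*children: "RuleExpr") -> "RuleExpr":
        return RuleExpr(and_=tuple(children))

    @staticmethod
    def any(*children: "RuleExpr") -> "RuleExpr":
        return RuleExpr(or_=tuple(children))

    @staticmethod
    def negate(child: "RuleExpr") -> "RuleExpr":
        return RuleExpr(not_=child)


class FactState:
    """Known classes (and optional numeric values) per endpoint.

    ``classes`` maps endpoint id to a frozenset of selected class labels --
    a single label for ordinary (single-choice) endpoints, possibly several
    for multi-choice classification branches.  ``values`` carries raw
    numeric measurements used by ``range_within`` atoms.  An endpoint
    absent from both mappings is unknown.
    """

    def __init__(
        self,
        classes: Optional[Mapping[str, Union[str, Iterable[str]]]] = None,
        values: Optional[Mapping[str, float]] = None,
    ) -> None:
        self.classes: dict = {}
        for eid, label in (classes or {}).items():
            self.assign(eid, label)
        self.values: dict = dict(values or {})

    def assign(self, endpoint_id: str, label: Union[str, Iterable[str]]) -> None:
        labels = frozenset([label]) if isinstance(label, str) else frozenset(label)
        if not labels:
            raise ValueError("cannot assign an empty class selection")
        self.classes[endpoint_id] = labels

    def single(self, endpoint_id: str) -> Optional[str]:
        labels = self.classes.get(endpoint_id)
        if labels is None:
            return None
        if len(labels) != 1:
            raise ValueError(
                f"endpoint {endpoint_id!r} has a multi-class selection {sorted(labels)}"
            )
        return next(iter(labels))

    def merged(self, other: "FactState") -> "FactState":
        """New state with ``other``'s assignments layered on top."""
        out = FactState()
        out.classes = {**self.classes, **other.classes}
        out.values = {**self.values, **other.values}
        return out

    def extends(self, other: "FactState") -> bool:
        return all(self.classes.get(k) == v for k, v in other.classes.items()) and all(
            self.values.get(k) == v for k, v in other.values.items()
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FactState)
            and self.classes == other.classes
            and self.values == other.values
        )

    def __repr__(self) -> str:
        return f"FactState(classes={self.classes!r}, values={self.values!r})"


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _interval_vs_range(interval, lo: float, hi: float) -> TruthValue:
    """Compare a class bin against a closed query range [lo, hi]."""
    if interval.subset_of(lo, hi):
        return TruthValue.TRUE
    if interval.disjoint_from(lo, hi):
        return TruthValue.FALSE
    return TruthValue.UNKNOWN


def eval_atom(atom: Atom, facts: FactState, kb: "KnowledgeBase") -> TruthValue:
    """Evaluate one atom; UNKNOWN when the endpoint is unassigned."""
    endpoint = kb.get_endpoint(atom.endpoint_id)  # raises on unknown id

    if atom.form in ("class_is", "class_in"):
        assigned = facts.classes.get(atom.endpoint_id)
        if assigned is None:
            return TruthValue.UNKNOWN
        wanted = (
            frozenset([atom.payload]) if atom.form == "class_is" else atom.payload
        )
        # membership over the selection; a non-empty selection that misses
        # every wanted label is a definite mismatch
        return TruthValue.TRUE if assigned & wanted else TruthValue.FALSE

    # range_within: prefer the raw value, fall back to the class bin
    lo, hi = atom.payload
    value = facts.values.get(atom.endpoint_id)
    if value is not None:
        return TruthValue.TRUE if lo <= value <= hi else TruthValue.FALSE
    assigned = facts.classes.get(atom.endpoint_id)
    if assigned is None:
        return TruthValue.UNKNOWN
    if endpoint.kind != "quantitative":
        raise RuleError(
            f"range_within atom on qualitative endpoint {atom.endpoint_id!r}"
        )
    verdicts = {
        _interval_vs_range(endpoint.class_interval(label), lo, hi)
        for label in assigned
    }
    if verdicts == {TruthValue.TRUE}:
        return TruthValue.TRUE
    if verdicts == {TruthValue.FALSE}:
        return TruthValue.FALSE
    return TruthValue.UNKNOWN


def eval_rule(expr: RuleExpr, facts: FactState, kb: "KnowledgeBase") -> TruthValue:
    """Kleene strong three-valued evaluation of a rule tree."""
    if expr.atom is not None:
        return eval_atom(expr.atom, facts, kb)
    if expr.not_ is not None:
        return ~eval_rule(expr.not_, facts, kb)
    if expr.and_ is not None:
        return min(eval_rule(c, facts, kb) for c in expr.and_)
    return max(eval_rule(c, facts, kb) for c in expr.or_)


def atoms_of(expr: RuleExpr):
    if expr.atom is not None:
        yield expr.atom
    elif expr.not_ is not None:
        yield from atoms_of(expr.not_)
    else:
        for child in expr.and_ or expr.or_:
            yield from atoms_of(child)


def endpoints_of(expr: RuleExpr) -> set:
    return {a.endpoint_id for a in atoms_of(expr)}


_ORACLE_CAP = 4096


def eval_rule_oracle(
    expr: RuleExpr, facts: FactState, kb: "KnowledgeBase"
) -> TruthValue:
    """Brute-force supervaluation oracle.

    Enumerates every completion of the unassigned endpoints over their full
    class sets and returns TRUE/FALSE only when the Kleene evaluation agrees
    across *all* completions.  Strictly more decisive than :func:`eval_rule`
    (it proves tautologies like ``A OR NOT A``) but exponential, hence a
    test oracle only.
    """
    unknown = sorted(
        eid
        for eid in endpoints_of(expr)
        if eid not in facts.classes and eid not in facts.values
    )
    label_sets = [
        [c.label for c in kb.get_endpoint(eid).classes] for eid in unknown
    ]
    n_completions = 1
    for labels in label_sets:
        n_completions *= len(labels)
        if n_completions > _ORACLE_CAP:
            raise RuleError(
                f"oracle enumeration exceeds cap ({_ORACLE_CAP}) for {unknown}"
            )
    verdicts = set()
    for combo in itertools.product(*label_sets):
        completed = FactState(values=facts.values)
        completed.classes = dict(facts.classes)
        for eid, label in zip(unknown, combo):
            completed.assign(eid, label)
        verdicts.add(eval_rule(expr, completed, kb))
        if len(verdicts) > 1:
            return TruthValue.UNKNOWN
    (verdict,) = verdicts
    return verdict


# ---------------------------------------------------------------------------
# explanation traces
# ---------------------------------------------------------------------------


@dataclass
class TraceNode:
    """A rule node annotated with its truth value.

    For atoms, ``observed`` records the fact consulted (selected classes or
    numeric value), or None when the endpoint was unassigned.
    """

    kind: str  # "atom" | "and" | "or" | "not"
    value: TruthValue
    atom: Optional[Atom] = None
    observed: Optional[object] = None
    children: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"kind": self.kind, "value": self.value.name}
        if self.atom is not None:
            out["atom"] = _atom_to_dict(self.atom)
            out["observed"] = (
                sorted(self.observed)
                if isinstance(self.observed, frozenset)
                else self.observed
            )
        if self.children:
            out["children"] = [c.to_dict() for c in self.children]
        return out


def explain(expr: RuleExpr, facts: FactState, kb: "KnowledgeBase") -> TraceNode:
    """Evaluate and return the annotated tree (the decision trace)."""
    if expr.atom is not None:
        atom = expr.atom
        observed: Optional[object] = facts.values.get(atom.endpoint_id)
        if observed is None:
            observed = facts.classes.get(atom.endpoint_id)
        return TraceNode(
            kind="atom",
            value=eval_atom(atom, facts, kb),
            atom=atom,
            observed=observed,
        )
    if expr.not_ is not None:
        child = explain(expr.not_, facts, kb)
        return TraceNode(kind="not", value=~child.value, children=[child])
    kind = "and" if expr.and_ is not None else "or"
    children = [explain(c, facts, kb) for c in (expr.and_ or expr.or_)]
    agg = min if kind == "and" else max
    return TraceNode(kind=kind, value=agg(c.value for c in children), children=children)


def false_atoms(trace: TraceNode) -> list:
    """Atoms to blame for the trace's definite FALSE (exclusion reasons).

    Returns ``(atom, negated)`` pairs: the atoms that force the root to be
    FALSE, where ``negated`` marks atoms sitting under an odd number of NOT
    nodes (the atom itself evaluated TRUE, and the rule demands it false).
    Empty when the root is not FALSE.
    """
    if trace.value is not TruthValue.FALSE:
        return []
    return _blame(trace, TruthValue.FALSE)


def _blame(node: TraceNode, want: TruthValue) -> list:
    if node.kind == "atom":
        return [(node.atom, want is TruthValue.TRUE)] if node.value is want else []
    if node.kind == "not":
        flipped = TruthValue.TRUE if want is TruthValue.FALSE else TruthValue.FALSE
        return _blame(node.children[0], flipped)
    out = []
    # a conjunction is FALSE because of its FALSE children (any one suffices);
    # a disjunction is FALSE only if *all* children are; dually for TRUE
    decisive = (node.kind == "and") == (want is TruthValue.FALSE)
    for child in node.children:
        if not decisive or child.value is want:
            out.extend(_blame(child, want))
    return out


# ---------------------------------------------------------------------------
# serialization (nested maps with keys and/or/not/atom)
# ---------------------------------------------------------------------------


def _atom_to_dict(atom: Atom) -> dict:
    d: dict = {"form": atom.form, "endpoint": atom.endpoint_id}
    if atom.form == "class_is":
        d["class"] = atom.payload
    elif atom.form == "class_in":
        d["classes"] = sorted(atom.payload)
    else:
        d["lower"], d["upper"] = atom.payload
    return d


def _atom_from_dict(d: Mapping) -> Atom:
    form = d.get("form")
    eid = d.get("endpoint")
    if form is None or eid is None:
        raise RuleError(f"atom needs 'form' and 'endpoint': {d!r}")
    if form == "class_is":
        return Atom("class_is", eid, d["class"])
    if form == "class_in":
        return Atom("class_in", eid, frozenset(d["classes"]))
    if form == "range_within":
        return Atom("range_within", eid, (d["lower"], d["upper"]))
    raise RuleError(f"unknown atom form {form!r}")


def rule_to_dict(expr: RuleExpr) -> dict:
    if expr.atom is not None:
        return {"atom": _atom_to_dict(expr.atom)}
    if expr.not_ is not None:
        return {"not": rule_to_dict(expr.not_)}
    if expr.and_ is not None:
        return {"and": [rule_to_dict(c) for c in expr.and_]}
    return {"or": [rule_to_dict(c) for c in expr.or_]}


def rule_from_dict(d: Mapping) -> RuleExpr:
    if not isinstance(d, Mapping) or len(d) != 1:
        raise RuleError(f"rule node must be a single-key map, got {d!r}")
    (key, payload), = d.items()
    if key == "atom":
        return RuleExpr(atom=_atom_from_dict(payload))
    if key == "not":
        return RuleExpr(not_=rule_from_dict(payload))
    if key in ("and", "or"):
        children = tuple(rule_from_dict(c) for c in payload)
        return RuleExpr(and_=children) if key == "and" else RuleExpr(or_=children)
    raise RuleError(f"unknown rule key {key!r}")
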