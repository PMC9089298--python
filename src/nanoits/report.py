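"""Render ITS results as text, Markdown, or schema-stable JSON.

The report answers the question experts asked of the original workshops:
*which decisional rules produced this recommendation?*  Every ranked assay
shows the four characteristic addends next to the total priority, and every
excluded assay cites the atom(s) of its applicability rule that evaluated
FALSE, together with the observed fact.  Payloads carry no timestamps, so
identical inputs render to identical bytes.
"""

from __future__ import annotations

import json
from typing import List

from .its import AssayVerdict, EndpointResult, ITSResult
from .kb import KnowledgeBase
from .rules import Atom

__all__ = ["render_trace_report", "export_report", "describe_atom", "FORMATS"]

FORMATS = ("text", "markdown", "json")


def describe_atom(atom: Atom, kb: KnowledgeBase) -> str:
    """One-line human reading of an atom, e.g. for exclusion reasons."""
    label = kb.get_endpoint(atom.endpoint_id).label if kb.has_endpoint(atom.endpoint_id) else atom.endpoint_id
    if atom.form == "class_is":
        return f"{atom.endpoint_id} ({label}) = {atom.payload}"
    if atom.form == "class_in":
        return f"{atom.endpoint_id} ({label}) in {{{', '.join(sorted(atom.payload))}}}"
    lo, hi = atom.payload
    unit = kb.get_endpoint(atom.endpoint_id).unit if kb.has_endpoint(atom.endpoint_id) else ""
    suffix = f" {unit}" if unit else ""
    return f"{atom.endpoint_id} ({label}) within [{lo:g}, {hi:g}]{suffix}"


def _exclusion_lines(verdict: AssayVerdict, kb: KnowledgeBase) -> List[str]:
    reasons = verdict.exclusion_reasons_with_polarity
    if not reasons:
        return ["applicability rule evaluated FALSE"]
    seen, lines = set(), []
    for atom, negated in reasons:
        desc = describe_atom(atom, kb)
        desc = f"required NOT ({desc})" if negated else f"failed: {desc}"
        if desc not in seen:
            seen.add(desc)
            lines.append(desc)
    return lines


def _entry_to_dict(entry: EndpointResult, kb: KnowledgeBase) -> dict:
    return {
        "scope": entry.scope,
        "module": entry.module_id,
        "endpoint": entry.endpoint_id,
        "groups": {
            group: [
                {
                    "rank": r.rank,
                    "assay": r.assay_id,
                    "name": kb.get_assay(r.assay_id).name,
                    "priority": r.priority,
                    "breakdown": dict(sorted(r.breakdown.items())),
                    "verdict": r.verdict,
                }
                for r in entry.group(group)
            ]
            for group in ("low", "medium_high")
        },
        "excluded": [
            {
                "assay": v.assay_id,
                "name": kb.get_assay(v.assay_id).name,
                "reasons": _exclusion_lines(v, kb),
                "trace": v.trace.to_dict() if v.trace is not None else None,
            }
            for v in entry.excluded
        ],
    }


def result_to_dict(result: ITSResult, kb: KnowledgeBase) -> dict:
    return {"entries": [_entry_to_dict(e, kb) for e in result.entries]}


_GROUP_TITLES = {"low": "low resolution", "medium_high": "medium-high resolution"}


def _render_lines(result: ITSResult, kb: KnowledgeBase, markdown: bool) -> List[str]:
    h = "## " if markdown else ""
    bullet = "- " if markdown else "  "
    lines: List[str] = []
    title = "Intelligent testing strategy report"
    lines.append(("# " if markdown else "") + title)
    total_excluded = sum(len(e.excluded) for e in result.entries)
    if total_excluded == 0:
        lines.append("No exclusions: every catalogued assay remains proposed.")
    lines.append("")
    for entry in result.entries:
        lines.append(f"{h}[{entry.scope}] {entry.module_id} / {entry.endpoint_id}")
        for group in ("low", "medium_high"):
            members = entry.group(group)
            if not members:
                continue
            lines.append(f"{'**' if markdown else ''}{_GROUP_TITLES[group]} assays{'**' if markdown else ''}:")
            for r in members:
                b = r.breakdown
                flag = " (possibly applicable: rule undecided)" if r.verdict == "possibly_applicable" else ""
                lines.append(
                    f"{bullet}{r.rank}. {r.assay_id} "
                    f"priority={r.priority} "
                    f"[duration {b['duration']} + cost {b['cost']} + "
                    f"(3-resolution) {b['resolution_penalty']} + expertise {b['expertise']}]"
                    f"{flag}"
                )
        if entry.excluded:
            lines.append(f"{'**' if markdown else ''}excluded{'**' if markdown else ''}:")
            for v in entry.excluded:
                for reason in _exclusion_lines(v, kb):
                    lines.append(f"{bullet}{v.assay_id}: {reason}")
        else:
            lines.append("no exclusions for this endpoint")
        lines.append("")
    return lines


def render_trace_report(
    result: ITSResult, kb: KnowledgeBase, format: str = "text"
) -> str:
    """Human-readable (text/markdown) or machine-readable (json) report."""
    return export_report(result, kb, format)


def export_report(result: ITSResult, kb: KnowledgeBase, format: str = "text") -> str:
    if format not in FORMATS:
        raise ValueError(f"unsupported format {format!r} (choose from {FORMATS})")
    if format == "json":
        return json.dumps(result_to_dict(result, kb), indent=2, sort_keys=True) + "\n"
    return "\n".join(_render_lines(result, kb, markdown=(format == "markdown"))) + "\n"
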