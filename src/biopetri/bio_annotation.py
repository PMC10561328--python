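"""Biological annotation of nets and generation of analysis reports.

An :class:`AnnotatedNet` attaches free-text meanings to places and
transitions (e.g. a place standing for a hormone pool or a symptom
state) together with an initial marking.  :func:`full_report` runs the
whole structural pipeline — incidence matrices, minimal S-/T-invariant
enumeration, coverage, reachability, conservation — and renders the
results with the biological labels attached, so interpretations such as
"every conserved place set contains these states" are derived from the
net, never hard-coded.

Terminology note: an S-invariant is a *conserved place set* (the
weighted token sum over its support never changes); it is not a pathway
or execution path, and reports deliberately use the conservation
wording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .behavior import (
    DEFAULT_MAX_MARKINGS,
    check_conservation,
    place_bounds,
    reachability_graph,
)
from .errors import KindError, UnknownIdentifierError
from .pn_core import Marking, PetriNetStructure
from .structure import (
    IncidenceTriple,
    Invariant,
    coverage,
    incidence_matrix,
    minimal_s_invariants,
    minimal_t_invariants,
)

__all__ = [
    "AnnotatedNet",
    "AnalysisReport",
    "annotate",
    "shared_support",
    "full_report",
]


@dataclass(frozen=True)
class AnnotatedNet:
    """A net plus biological labels and an initial marking.

    Labels missing from the input maps default to the identifier itself,
    so the label maps always cover exactly the net's elements.
    """

    net: PetriNetStructure
    place_labels: dict[str, str]
    transition_labels: dict[str, str]
    initial: Marking

    def label(self, identifier: str) -> str:
        if identifier in self.place_labels:
            return self.place_labels[identifier]
        if identifier in self.transition_labels:
            return self.transition_labels[identifier]
        raise UnknownIdentifierError(f"unknown element {identifier!r}")

    def labeled(self, identifiers) -> list[str]:
        """Labels for a collection of ids, in net declaration order."""
        order = {p: i for i, p in enumerate(self.net.places)}
        order.update(
            {t: i + self.net.n_places for i, t in enumerate(self.net.transitions)}
        )
        return [self.label(i) for i in sorted(identifiers, key=order.__getitem__)]


def annotate(
    net: PetriNetStructure,
    place_labels: Mapping[str, str] | None = None,
    transition_labels: Mapping[str, str] | None = None,
    initial: Marking | Sequence[int] | None = None,
) -> AnnotatedNet:
    """Build an :class:`AnnotatedNet`, filling label defaults.

    Raises
    ------
    UnknownIdentifierError
        If a label refers to an element the net does not declare.
    """
    place_labels = dict(place_labels or {})
    transition_labels = dict(transition_labels or {})
    for p in place_labels:
        if p not in net.places:
            raise UnknownIdentifierError(f"label given for unknown place {p!r}")
    for t in transition_labels:
        if t not in net.transitions:
            raise UnknownIdentifierError(f"label given for unknown transition {t!r}")
    full_places = {p: place_labels.get(p, p) for p in net.places}
    full_transitions = {t: transition_labels.get(t, t) for t in net.transitions}
    if initial is None:
        initial = Marking([0] * net.n_places)
    initial = Marking.coerce(initial)
    if len(initial) != net.n_places:
        raise UnknownIdentifierError(
            f"initial marking has {len(initial)} entries for {net.n_places} places"
        )
    return AnnotatedNet(
        net=net,
        place_labels=full_places,
        transition_labels=full_transitions,
        initial=initial,
    )


def shared_support(invariants: Sequence[Invariant]) -> set[str]:
    """Intersection of the supports of a family of S-invariants.

    Empty input yields the empty set (no claim of commonality).
    """
    kinds = {inv.kind for inv in invariants}
    if kinds - {"S"}:
        raise KindError("shared_support expects S-kind invariants only")
    if not invariants:
        return set()
    common = set(invariants[0].support)
    for inv in invariants[1:]:
        common &= inv.support
    return common


@dataclass(frozen=True)
class AnalysisReport:
    """Full structural/behavioral analysis with labels attached.

    Serializes deterministically to JSON (schema documented in the
    repository README) and to Markdown.
    """

    incidence: IncidenceTriple
    s_invariants: tuple[Invariant, ...]
    t_invariants: tuple[Invariant, ...]
    shared_support: tuple[str, ...]          # place ids, net order
    shared_support_labels: tuple[str, ...]
    uncovered_places: tuple[str, ...]
    uncovered_transitions: tuple[str, ...]
    reachability_summary: dict
    warnings: tuple[str, ...]
    annotated: AnnotatedNet = field(repr=False)

    def _invariant_entry(self, inv: Invariant) -> dict:
        annotated = self.annotated
        ids = (
            annotated.net.places if inv.kind == "S" else annotated.net.transitions
        )
        order = {x: i for i, x in enumerate(ids)}
        support = sorted(inv.support, key=order.__getitem__)
        return {
            "kind": inv.kind,
            "vector": list(inv.vector),
            "support": support,
            "support_labels": [annotated.label(x) for x in support],
            "normalized": inv.normalized,
        }

    def to_json_dict(self) -> dict:
        ann = self.annotated
        return {
            "net": {
                "places": list(ann.net.places),
                "place_labels": {p: ann.place_labels[p] for p in ann.net.places},
                "transitions": list(ann.net.transitions),
                "transition_labels": {
                    t: ann.transition_labels[t] for t in ann.net.transitions
                },
                "initial_marking": list(ann.initial.counts),
            },
            "incidence": {
                "row_order": "transitions",
                "column_order": "places",
                "a_minus": self.incidence.a_minus.tolist(),
                "a_plus": self.incidence.a_plus.tolist(),
                "a": self.incidence.a.tolist(),
            },
            "s_invariants": [self._invariant_entry(i) for i in self.s_invariants],
            "t_invariants": [self._invariant_entry(i) for i in self.t_invariants],
            "shared_support": {
                "places": list(self.shared_support),
                "labels": list(self.shared_support_labels),
            },
            "uncovered": {
                "places": list(self.uncovered_places),
                "place_labels": [ann.label(p) for p in self.uncovered_places],
                "transitions": list(self.uncovered_transitions),
                "transition_labels": [
                    ann.label(t) for t in self.uncovered_transitions
                ],
            },
            "reachability": self.reachability_summary,
            "warnings": list(self.warnings),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_json_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        ann = self.annotated
        lines = ["# Net analysis report", ""]
        lines.append(
            f"Net with {ann.net.n_places} places and "
            f"{ann.net.n_transitions} transitions; initial marking "
            f"{tuple(ann.initial.counts)}."
        )
        lines.append("")
        lines.append("## Conserved place sets (minimal S-invariants)")
        if self.s_invariants:
            for inv in self.s_invariants:
                entry = self._invariant_entry(inv)
                lines.append(
                    f"- vector {tuple(inv.vector)}; support: "
                    + ", ".join(
                        f"{p} ({lbl})"
                        for p, lbl in zip(entry["support"], entry["support_labels"])
                    )
                )
            if self.shared_support:
                labeled = ", ".join(self.shared_support_labels)
                lines.append("")
                lines.append(
                    "Every conserved place set contains: "
                    + ", ".join(self.shared_support)
                    + f" — {labeled}. The token sums over these shared states "
                    "are maintained by every execution, indicating that all "
                    "conserved routes pass through them."
                )
        else:
            lines.append("- none found")
        lines.append("")
        lines.append("## Minimal T-invariants")
        if self.t_invariants:
            for inv in self.t_invariants:
                entry = self._invariant_entry(inv)
                lines.append(
                    f"- vector {tuple(inv.vector)}; support: "
                    + ", ".join(entry["support"])
                )
        else:
            lines.append(
                "- none found (no firing-count vector reproduces a marking; "
                "every run is transient)"
            )
        lines.append("")
        lines.append("## Coverage")
        lines.append(
            "- uncovered places: "
            + (
                ", ".join(
                    f"{p} ({ann.label(p)})" for p in self.uncovered_places
                )
                or "none"
            )
        )
        lines.append(
            "- uncovered transitions: "
            + (", ".join(self.uncovered_transitions) or "none")
        )
        lines.append("")
        lines.append("## Reachability")
        rs = self.reachability_summary
        status = "partial (truncated)" if rs["truncated"] else "complete"
        lines.append(f"- exploration: {status}")
        lines.append(f"- reachable markings: {rs['n_markings']}")
        lines.append(f"- dead markings: {rs['n_dead']}")
        if rs.get("place_bounds") is not None:
            lines.append(f"- place bounds: {tuple(rs['place_bounds'])}")
        if rs.get("conservation_holds") is not None:
            lines.append(
                "- S-invariant conservation over all reachable markings: "
                + ("holds" if rs["conservation_holds"] else "VIOLATED")
            )
        if self.warnings:
            lines.append("")
            lines.append("## Warnings")
            lines.extend(f"- {w}" for w in self.warnings)
        return "\n".join(lines) + "\n"


def full_report(
    annotated: AnnotatedNet, max_markings: int = DEFAULT_MAX_MARKINGS
) -> AnalysisReport:
    """Run the complete analysis pipeline on an annotated net.

    Truncated reachability marks the summary as partial; it is not an
    error.
    """
    net = annotated.net
    triple = incidence_matrix(net)
    s_invs = tuple(minimal_s_invariants(net))
    t_invs = tuple(minimal_t_invariants(net))
    _, uncovered_p = coverage(net, "S")
    _, uncovered_t = coverage(net, "T")
    place_order = {p: i for i, p in enumerate(net.places)}
    trans_order = {t: i for i, t in enumerate(net.transitions)}
    shared = sorted(shared_support(list(s_invs)), key=place_order.__getitem__)

    graph = reachability_graph(net, annotated.initial, max_markings=max_markings)
    summary: dict = {
        "truncated": graph.truncated,
        "n_markings": graph.n_nodes,
        "n_dead": graph.n_dead,
        "place_bounds": None,
        "conservation_holds": None,
        "conserved_values": None,
    }
    if not graph.truncated:
        summary["place_bounds"] = list(place_bounds(graph))
        summary["conservation_holds"] = check_conservation(graph, s_invs)
        summary["conserved_values"] = [
            sum(w * c for w, c in zip(inv.vector, annotated.initial.counts))
            for inv in s_invs
        ]

    warnings = []
    if net.has_self_loop():
        warnings.append(
            "net contains self-loop arc pairs; the incidence matrix A = A+ - A- "
            "cancels them, so invariants computed from A ignore self-loop "
            "structure"
        )
    if graph.truncated:
        warnings.append(
            f"reachability exploration truncated at {max_markings} markings; "
            "behavioral summary is partial"
        )

    return AnalysisReport(
        incidence=triple,
        s_invariants=s_invs,
        t_invariants=t_invs,
        shared_support=tuple(shared),
        shared_support_labels=tuple(annotated.label(p) for p in shared),
        uncovered_places=tuple(sorted(uncovered_p, key=place_order.__getitem__)),
        uncovered_transitions=tuple(sorted(uncovered_t, key=trans_order.__getitem__)),
        reachability_summary=summary,
        warnings=tuple(warnings),
        annotated=annotated,
    )
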