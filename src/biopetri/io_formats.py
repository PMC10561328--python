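"""Reading and writing net interchange formats.

Two formats are supported, both plain text:

* **PNML** — the ISO/IEC 15909-2 place/transition XML interchange
  format, as consumed and produced by mainstream Petri net tools.
  Only the PT-net subset is handled; unknown or tool-specific subtrees
  are ignored with a logged warning.
* **Matrix text** — a minimal three-section format holding the place
  list (with labels and initial tokens), the transition list (with
  labels), and the integer input/output matrices A⁻ and A⁺ with rows =
  transitions and columns = places.  A⁻ and A⁺ are stored separately —
  never only their difference — so self-loop arcs survive round-trips.

Matrix text grammar (tab-separated, ``#`` lines are comments)::

    PLACES
    <place-id> TAB <initial-tokens> TAB <label>
    ...
    TRANSITIONS
    <transition-id> TAB <label>
    ...
    A_MINUS
    <row of integers, one per place>      # one row per transition
    ...
    A_PLUS
    <row of integers, one per place>
    ...

Both round-trips preserve places, transitions, arcs, weights, labels and
the initial marking exactly.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from pathlib import Path

from .bio_annotation import AnnotatedNet, annotate
from .errors import FormatError
from .pn_core import Marking, PetriNetStructure
from .structure import input_matrix, output_matrix

__all__ = [
    "write_pnml",
    "read_pnml",
    "to_pnml",
    "to_matrix_text",
    "write_matrix_text",
    "read_matrix_text",
]

logger = logging.getLogger(__name__)

PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
PTNET_TYPE = "http://www.pnml.org/version-2009/grammar/ptnet"
TOOL_NAME = "biopetri"

_NCNAME_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


def _ncname(identifier: str) -> str:
    """Sanitize an identifier into an XML NCName."""
    if _NCNAME_OK.match(identifier):
        return identifier
    cleaned = re.sub(r"[^A-Za-z0-9_.\-]", "_", identifier)
    if not cleaned or not re.match(r"[A-Za-z_]", cleaned[0]):
        cleaned = "id_" + cleaned
    return cleaned


def _q(tag: str) -> str:
    return f"{{{PNML_NS}}}{tag}"


def _text_child(parent: ET.Element, tag: str, text: str) -> None:
    holder = ET.SubElement(parent, _q(tag))
    ET.SubElement(holder, _q("text")).text = text


def _original_id(parent: ET.Element, identifier: str) -> None:
    tool = ET.SubElement(
        parent, _q("toolspecific"), tool=TOOL_NAME, version="0.1"
    )
    ET.SubElement(tool, _q("originalId")).text = identifier


def to_pnml(annotated: AnnotatedNet) -> str:
    """Render an annotated net as an ISO/IEC 15909-2 PT-net document.

    Identifiers are sanitized into NCNames; when sanitization changes an
    id the original is kept in a tool-specific subtree so reading the
    file back restores it.  Biological labels go into ``name`` elements
    and place initial markings come from the annotated initial marking.
    """
    net = annotated.net
    used: dict[str, str] = {}

    def unique_id(identifier: str) -> str:
        base = _ncname(identifier)
        candidate, k = base, 1
        while candidate in used and used[candidate] != identifier:
            candidate = f"{base}_{k}"
            k += 1
        used[candidate] = identifier
        return candidate

    ET.register_namespace("", PNML_NS)
    root = ET.Element(_q("pnml"))
    net_el = ET.SubElement(root, _q("net"), id="net1", type=PTNET_TYPE)
    page = ET.SubElement(net_el, _q("page"), id="page1")

    ids = {x: unique_id(x) for x in (*net.places, *net.transitions)}
    for j, p in enumerate(net.places):
        el = ET.SubElement(page, _q("place"), id=ids[p])
        _text_child(el, "name", annotated.place_labels[p])
        tokens = annotated.initial[j]
        if tokens:
            _text_child(el, "initialMarking", str(tokens))
        if ids[p] != p:
            _original_id(el, p)
    for t in net.transitions:
        el = ET.SubElement(page, _q("transition"), id=ids[t])
        _text_child(el, "name", annotated.transition_labels[t])
        if ids[t] != t:
            _original_id(el, t)
    arc_n = 0
    for src, dst, w in annotated.net.arcs():
        arc_n += 1
        el = ET.SubElement(
            page, _q("arc"), id=f"arc{arc_n}", source=ids[src], target=ids[dst]
        )
        if w != 1:
            _text_child(el, "inscription", str(w))

    ET.indent(root)
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )


def write_pnml(annotated: AnnotatedNet, path) -> None:
    """Write :func:`to_pnml` output to ``path``."""
    Path(path).write_text(to_pnml(annotated), encoding="utf-8")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_text(el: ET.Element, tag: str) -> str | None:
    for child in el:
        if _local(child.tag) == tag:
            for sub in child:
                if _local(sub.tag) == "text":
                    return sub.text or ""
    return None


def _restore_id(el: ET.Element) -> str | None:
    for child in el:
        if _local(child.tag) == "toolspecific" and child.get("tool") == TOOL_NAME:
            for sub in child.iter():
                if _local(sub.tag) == "originalId":
                    return sub.text
    return None


_KNOWN_CHILDREN = {"name", "initialMarking", "inscription", "graphics", "toolspecific"}


def read_pnml(path) -> AnnotatedNet:
    """Parse a PT-net PNML document into an annotated net.

    Missing ``initialMarking`` means 0 tokens; missing arc
    ``inscription`` means weight 1.  Unrecognized subtrees (graphics,
    foreign tool extensions) are skipped with a logged warning.

    Raises
    ------
    FormatError
        On malformed XML (with line context), non-bipartite arcs,
        negative markings, or dangling arc references.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML at line {exc.position[0]}") from exc
    root = tree.getroot()
    net_el = next((el for el in root.iter() if _local(el.tag) == "net"), None)
    if net_el is None:
        raise FormatError(f"{path}: no <net> element found")

    places: list[str] = []
    transitions: list[str] = []
    place_labels: dict[str, str] = {}
    transition_labels: dict[str, str] = {}
    initial: dict[str, int] = {}
    arcs: list[tuple[str, str, int]] = []

    for el in net_el.iter():
        kind = _local(el.tag)
        if kind not in ("place", "transition", "arc"):
            continue
        for child in el:
            if _local(child.tag) not in _KNOWN_CHILDREN:
                logger.warning(
                    "%s: ignoring unrecognized <%s> inside <%s>",
                    path,
                    _local(child.tag),
                    kind,
                )
        if kind == "place":
            pid = _restore_id(el) or el.get("id")
            if pid is None:
                raise FormatError(f"{path}: <place> without id")
            places.append(pid)
            label = _read_text(el, "name")
            if label is not None:
                place_labels[pid] = label
            tokens_text = _read_text(el, "initialMarking")
            tokens = int(tokens_text) if tokens_text else 0
            if tokens < 0:
                raise FormatError(
                    f"{path}: place {pid!r} has negative initial marking {tokens}"
                )
            initial[pid] = tokens
        elif kind == "transition":
            tid = _restore_id(el) or el.get("id")
            if tid is None:
                raise FormatError(f"{path}: <transition> without id")
            transitions.append(tid)
            label = _read_text(el, "name")
            if label is not None:
                transition_labels[tid] = label
        else:
            src, dst = el.get("source"), el.get("target")
            if src is None or dst is None:
                raise FormatError(f"{path}: <arc> missing source/target")
            w_text = _read_text(el, "inscription")
            w = int(w_text) if w_text else 1
            if w < 1:
                raise FormatError(f"{path}: arc {src}->{dst} has weight {w} < 1")
            arcs.append((src, dst, w))

    raw_to_id = {}
    for el in net_el.iter():
        if _local(el.tag) in ("place", "transition"):
            raw_to_id[el.get("id")] = _restore_id(el) or el.get("id")

    pset, tset = set(places), set(transitions)
    pre: dict[tuple[str, str], int] = {}
    post: dict[tuple[str, str], int] = {}
    for src_raw, dst_raw, w in arcs:
        src = raw_to_id.get(src_raw, src_raw)
        dst = raw_to_id.get(dst_raw, dst_raw)
        if src in pset and dst in tset:
            pre[(dst, src)] = pre.get((dst, src), 0) + w
        elif src in tset and dst in pset:
            post[(src, dst)] = post.get((src, dst), 0) + w
        else:
            raise FormatError(
                f"{path}: arc {src!r} -> {dst!r} does not connect a place "
                "and a transition"
            )

    net = PetriNetStructure(places, transitions, pre, post)
    return annotate(
        net,
        place_labels=place_labels,
        transition_labels=transition_labels,
        initial=Marking([initial[p] for p in places]),
    )


def to_matrix_text(annotated: AnnotatedNet) -> str:
    """Render the three-section matrix text format (see module docs)."""
    net = annotated.net
    a_minus = input_matrix(net)
    a_plus = output_matrix(net)
    lines = ["# biopetri matrix net v1", "PLACES"]
    for j, p in enumerate(net.places):
        label = annotated.place_labels[p]
        if "\t" in p or "\t" in label or "\n" in label:
            raise FormatError("identifiers and labels must not contain tabs/newlines")
        lines.append(f"{p}\t{annotated.initial[j]}\t{label}")
    lines.append("TRANSITIONS")
    for t in net.transitions:
        label = annotated.transition_labels[t]
        if "\t" in t or "\t" in label or "\n" in label:
            raise FormatError("identifiers and labels must not contain tabs/newlines")
        lines.append(f"{t}\t{label}")
    lines.append("A_MINUS")
    for row in a_minus:
        lines.append("\t".join(str(int(v)) for v in row))
    lines.append("A_PLUS")
    for row in a_plus:
        lines.append("\t".join(str(int(v)) for v in row))
    return "\n".join(lines) + "\n"


def write_matrix_text(annotated: AnnotatedNet, path) -> None:
    """Write the three-section matrix text format to ``path``."""
    Path(path).write_text(to_matrix_text(annotated), encoding="utf-8")


def read_matrix_text(path) -> AnnotatedNet:
    """Read the three-section matrix text format back into a net.

    Raises
    ------
    FormatError
        On missing sections, dimension mismatches between the element
        lists and the matrices, or non-integer cells.
    """
    text = Path(path).read_text(encoding="utf-8")
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip() in ("PLACES", "TRANSITIONS", "A_MINUS", "A_PLUS"):
            current = line.strip()
            sections[current] = []
            continue
        if current is None:
            raise FormatError(f"{path}:{lineno}: content before any section header")
        sections[current].append((lineno, line))

    for required in ("PLACES", "TRANSITIONS", "A_MINUS", "A_PLUS"):
        if required not in sections:
            raise FormatError(f"{path}: missing section {required}")

    places, initial, place_labels = [], [], {}
    for lineno, line in sections["PLACES"]:
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: PLACES row needs id and tokens")
        pid = fields[0]
        try:
            tokens = int(fields[1])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: invalid token count {fields[1]!r}"
            ) from None
        places.append(pid)
        initial.append(tokens)
        if len(fields) >= 3:
            place_labels[pid] = fields[2]

    transitions, transition_labels = [], {}
    for lineno, line in sections["TRANSITIONS"]:
        fields = line.split("\t")
        transitions.append(fields[0])
        if len(fields) >= 2:
            transition_labels[fields[0]] = fields[1]

    def parse_matrix(name: str) -> list[list[int]]:
        rows = []
        for lineno, line in sections[name]:
            try:
                row = [int(v) for v in line.split("\t")]
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer cell in {name}"
                ) from None
            if len(row) != len(places):
                raise FormatError(
                    f"{path}:{lineno}: {name} row has {len(row)} cells for "
                    f"{len(places)} places"
                )
            if any(v < 0 for v in row):
                raise FormatError(f"{path}:{lineno}: negative weight in {name}")
            rows.append(row)
        if len(rows) != len(transitions):
            raise FormatError(
                f"{path}: {name} has {len(rows)} rows for "
                f"{len(transitions)} transitions"
            )
        return rows

    a_minus = parse_matrix("A_MINUS")
    a_plus = parse_matrix("A_PLUS")

    pre = {
        (t, p): a_minus[i][j]
        for i, t in enumerate(transitions)
        for j, p in enumerate(places)
        if a_minus[i][j] > 0
    }
    post = {
        (t, p): a_plus[i][j]
        for i, t in enumerate(transitions)
        for j, p in enumerate(places)
        if a_plus[i][j] > 0
    }
    net = PetriNetStructure(places, transitions, pre, post)
    return annotate(
        net,
        place_labels=place_labels,
        transition_labels=transition_labels,
        initial=Marking(initial),
    )
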