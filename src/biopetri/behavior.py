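"""Exhaustive behavioral analysis: reachability, deadlock, boundedness.

The reachability graph enumerates every marking reachable from an
initial marking by breadth-first search, firing transitions in index
order so the node and edge orderings are deterministic.  Unbounded nets
are legal inputs: exploration stops after ``max_markings`` distinct
markings and flags the graph as truncated instead of raising.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

from .errors import CompletenessError, KindError
from .pn_core import Marking, PetriNetStructure, enabled_set, fire
from .structure import Invariant

__all__ = [
    "ReachabilityGraph",
    "reachability_graph",
    "place_bounds",
    "check_conservation",
    "graph_to_dot",
    "write_edge_tsv",
]

DEFAULT_MAX_MARKINGS = 100_000


@dataclass(frozen=True)
class ReachabilityGraph:
    """Reachable markings as nodes, fired transitions as labeled edges.

    ``dead`` is exact (markings with no enabled transition) only when
    ``truncated`` is False; on a truncated graph unexplored frontier
    nodes are not classified.
    """

    nodes: tuple[Marking, ...]
    edges: tuple[tuple[Marking, str, Marking], ...]
    initial: Marking
    dead: tuple[Marking, ...]
    truncated: bool

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_dead(self) -> int:
        return len(self.dead)

    def has_cycle(self) -> bool:
        """Directed-cycle test by iterative DFS (three-color)."""
        adjacency: dict[tuple[int, ...], list[tuple[int, ...]]] = {
            n.counts: [] for n in self.nodes
        }
        for src, _, dst in self.edges:
            adjacency[src.counts].append(dst.counts)
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {n: WHITE for n in adjacency}
        for start in adjacency:
            if color[start] != WHITE:
                continue
            stack: list[tuple[tuple[int, ...], int]] = [(start, 0)]
            color[start] = GRAY
            while stack:
                node, i = stack[-1]
                if i < len(adjacency[node]):
                    stack[-1] = (node, i + 1)
                    child = adjacency[node][i]
                    if color[child] == GRAY:
                        return True
                    if color[child] == WHITE:
                        color[child] = GRAY
                        stack.append((child, 0))
                else:
                    color[node] = BLACK
                    stack.pop()
        return False


def reachability_graph(
    net: PetriNetStructure,
    m0: Marking,
    max_markings: int = DEFAULT_MAX_MARKINGS,
) -> ReachabilityGraph:
    """Breadth-first exploration of the reachable state space.

    Transitions are fired in index order at each marking.  If more than
    ``max_markings`` distinct markings exist, exploration stops and the
    graph is flagged truncated (never an error).
    """
    if max_markings < 1:
        raise ValueError("max_markings must be >= 1")
    m0 = Marking.coerce(m0)
    seen: dict[tuple[int, ...], Marking] = {m0.counts: m0}
    order: list[Marking] = [m0]
    edges: list[tuple[Marking, str, Marking]] = []
    queue: deque[Marking] = deque([m0])
    truncated = False
    expanded: set[tuple[int, ...]] = set()
    while queue:
        m = queue.popleft()
        expanded.add(m.counts)
        for t in enabled_set(net, m):
            m2 = fire(net, m, t)
            if m2.counts not in seen:
                if len(seen) >= max_markings:
                    truncated = True
                    continue
                seen[m2.counts] = m2
                order.append(m2)
                queue.append(m2)
            edges.append((m, t, seen[m2.counts]))
    has_out = {src.counts for src, _, _ in edges}
    dead = tuple(
        n for n in order if n.counts not in has_out and n.counts in expanded
    ) if not truncated else tuple(
        n for n in order if n.counts not in has_out and n.counts in expanded
        and not enabled_set(net, n)
    )
    return ReachabilityGraph(
        nodes=tuple(order),
        edges=tuple(edges),
        initial=m0,
        dead=dead,
        truncated=truncated,
    )


def place_bounds(graph: ReachabilityGraph) -> tuple[int, ...]:
    """Componentwise maximum token count over all reachable markings."""
    if graph.truncated:
        raise CompletenessError(
            "place bounds require a complete (non-truncated) reachability graph"
        )
    return tuple(max(col) for col in zip(*(n.counts for n in graph.nodes)))


def check_conservation(
    graph: ReachabilityGraph, invariants: Sequence[Invariant]
) -> bool:
    """True iff every S-invariant's weighted token sum is identical at
    every node of the graph (conserved from the initial marking)."""
    for inv in invariants:
        if inv.kind != "S":
            raise KindError("conservation check requires S-kind invariants")
        target = sum(w * c for w, c in zip(inv.vector, graph.initial.counts))
        for node in graph.nodes:
            if sum(w * c for w, c in zip(inv.vector, node.counts)) != target:
                return False
    return True


def _marking_label(m: Marking) -> str:
    return "(" + ",".join(str(c) for c in m.counts) + ")"


def graph_to_dot(graph: ReachabilityGraph) -> str:
    """Render the graph as GraphViz DOT; node label = marking vector,
    edge label = fired transition."""
    lines = ["digraph reachability {"]
    for n in graph.nodes:
        attrs = f'label="{_marking_label(n)}"'
        if n == graph.initial:
            attrs += ' shape="doublecircle"'
        elif n in graph.dead:
            attrs += ' shape="box"'
        lines.append(f'  "{_marking_label(n)}" [{attrs}];')
    for src, t, dst in graph.edges:
        lines.append(
            f'  "{_marking_label(src)}" -> "{_marking_label(dst)}" [label="{t}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_edge_tsv(graph: ReachabilityGraph, path) -> None:
    """Edge list as TSV: source marking, transition, target marking."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttransition\ttarget\n")
        for src, t, dst in graph.edges:
            fh.write(f"{_marking_label(src)}\t{t}\t{_marking_label(dst)}\n")
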