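"""Place/transition net data model and token-game semantics.

A net is a bipartite structure of *places* (token holders) and
*transitions* (events) connected by weighted arcs.  A :class:`Marking`
assigns a nonnegative integer token count to every place; firing an
enabled transition consumes ``pre`` tokens from its input places and
produces ``post`` tokens on its output places.

Conventions
-----------
* Place and transition identifiers are strings; the two identifier sets
  must be disjoint and their union nonempty.
* Arc weights are positive integers.  Ordinary nets (all weights 1) are
  the common biological case, but weighted arcs are supported so the
  same machinery covers stoichiometric models.
* A transition with an empty pre-set is a *source* transition and is
  enabled at every marking.  Such nets are unbounded; they are legal
  inputs here and handled downstream by truncation flags.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import (
    DimensionError,
    NetDefinitionError,
    NotEnabledError,
    UnknownIdentifierError,
)

__all__ = [
    "PetriNetStructure",
    "Marking",
    "Trace",
    "is_enabled",
    "enabled_set",
    "fire",
    "fire_sequence",
    "random_run",
    "is_dead",
]

ArcMap = Mapping[tuple[str, str], int]


@dataclass(frozen=True)
class PetriNetStructure:
    """Immutable place/transition net structure.

    Parameters
    ----------
    places : sequence of str
        Ordered place identifiers; the order fixes marking/vector indexing.
    transitions : sequence of str
        Ordered transition identifiers, disjoint from ``places``.
    pre : mapping (transition, place) -> weight
        Input-arc weights (place → transition); absent pairs mean weight 0.
    post : mapping (transition, place) -> weight
        Output-arc weights (transition → place); absent pairs mean weight 0.
    """

    places: tuple[str, ...]
    transitions: tuple[str, ...]
    pre: dict[tuple[str, str], int]
    post: dict[tuple[str, str], int]

    def __init__(
        self,
        places: Sequence[str],
        transitions: Sequence[str],
        pre: ArcMap | None = None,
        post: ArcMap | None = None,
    ):
        places = tuple(places)
        transitions = tuple(transitions)
        pre = dict(pre or {})
        post = dict(post or {})
        self._validate(places, transitions, pre, post)
        object.__setattr__(self, "places", places)
        object.__setattr__(self, "transitions", transitions)
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)
        object.__setattr__(self, "_place_index", {p: i for i, p in enumerate(places)})
        object.__setattr__(
            self, "_transition_index", {t: i for i, t in enumerate(transitions)}
        )

    @staticmethod
    def _validate(places, transitions, pre, post):
        if len(set(places)) != len(places):
            raise NetDefinitionError("duplicate place identifiers")
        if len(set(transitions)) != len(transitions):
            raise NetDefinitionError("duplicate transition identifiers")
        if set(places) & set(transitions):
            raise NetDefinitionError(
                "place and transition identifier sets must be disjoint"
            )
        if not places and not transitions:
            raise NetDefinitionError("net must contain at least one place or transition")
        pset, tset = set(places), set(transitions)
        for name, arcmap in (("pre", pre), ("post", post)):
            for (t, p), w in arcmap.items():
                if t not in tset:
                    raise UnknownIdentifierError(
                        f"{name} arc references unknown transition {t!r}"
                    )
                if p not in pset:
                    raise UnknownIdentifierError(
                        f"{name} arc references unknown place {p!r}"
                    )
                if not isinstance(w, int) or w < 1:
                    raise NetDefinitionError(
                        f"{name} arc ({t!r}, {p!r}) has non-positive weight {w!r}"
                    )

    # -- index helpers -------------------------------------------------

    @property
    def n_places(self) -> int:
        return len(self.places)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def place_index(self, p: str) -> int:
        try:
            return self._place_index[p]
        except KeyError:
            raise UnknownIdentifierError(f"unknown place {p!r}") from None

    def transition_index(self, t: str) -> int:
        try:
            return self._transition_index[t]
        except KeyError:
            raise UnknownIdentifierError(f"unknown transition {t!r}") from None

    def pre_weight(self, t: str, p: str) -> int:
        return self.pre.get((t, p), 0)

    def post_weight(self, t: str, p: str) -> int:
        return self.post.get((t, p), 0)

    def preset(self, t: str) -> tuple[str, ...]:
        """Input places of ``t`` in place order."""
        self.transition_index(t)
        return tuple(p for p in self.places if (t, p) in self.pre)

    def postset(self, t: str) -> tuple[str, ...]:
        """Output places of ``t`` in place order."""
        self.transition_index(t)
        return tuple(p for p in self.places if (t, p) in self.post)

    def has_self_loop(self) -> bool:
        """True when some (transition, place) pair carries both an input
        and an output arc, in which case the plain incidence matrix loses
        structural information."""
        return any(key in self.post for key in self.pre)

    def arcs(self) -> list[tuple[str, str, int]]:
        """All arcs as (source, target, weight), places↔transitions."""
        out = [(p, t, w) for (t, p), w in self.pre.items()]
        out += [(t, p, w) for (t, p), w in self.post.items()]
        return out


@dataclass(frozen=True)
class Marking:
    """Token counts per place, in the net's canonical place order."""

    counts: tuple[int, ...]

    def __init__(self, counts: Iterable[int]):
        counts = tuple(int(c) for c in counts)
        if any(c < 0 for c in counts):
            raise NetDefinitionError("marking entries must be nonnegative")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __getitem__(self, i: int) -> int:
        return self.counts[i]

    def __iter__(self):
        return iter(self.counts)

    def total(self) -> int:
        return sum(self.counts)

    @classmethod
    def coerce(cls, value: "Marking | Iterable[int]") -> "Marking":
        return value if isinstance(value, Marking) else cls(value)


def _check_marking(net: PetriNetStructure, m: Marking) -> Marking:
    m = Marking.coerce(m)
    if len(m) != net.n_places:
        raise DimensionError(
            f"marking has {len(m)} entries but net has {net.n_places} places"
        )
    return m


@dataclass(frozen=True)
class Trace:
    """Record of a run: initial marking plus (transition, marking) steps."""

    initial: Marking
    steps: tuple[tuple[str, Marking], ...]
    terminated_dead: bool
    seed: int | None = field(default=None)

    @property
    def final(self) -> Marking:
        return self.steps[-1][1] if self.steps else self.initial

    @property
    def transitions_fired(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.steps)

    def __len__(self) -> int:
        return len(self.steps)


def is_enabled(net: PetriNetStructure, m: Marking, t: str) -> bool:
    """True iff every input place of ``t`` holds at least the arc weight."""
    m = _check_marking(net, m)
    net.transition_index(t)
    return all(
        m[net.place_index(p)] >= w for (tt, p), w in net.pre.items() if tt == t
    )


def _deficient_places(net: PetriNetStructure, m: Marking, t: str) -> list[str]:
    return [
        p
        for p in net.places
        if (t, p) in net.pre and m[net.place_index(p)] < net.pre[(t, p)]
    ]


def enabled_set(net: PetriNetStructure, m: Marking) -> list[str]:
    """Enabled transitions, in transition-index order (deterministic)."""
    m = _check_marking(net, m)
    return [t for t in net.transitions if is_enabled(net, m, t)]


def fire(net: PetriNetStructure, m: Marking, t: str) -> Marking:
    """Fire ``t`` at ``m``: per place, subtract the pre weight and add the
    post weight.  Places outside the pre/post sets are unchanged.

    Raises
    ------
    NotEnabledError
        If ``t`` is disabled; the error names the deficient places.
    """
    m = _check_marking(net, m)
    net.transition_index(t)
    deficient = _deficient_places(net, m, t)
    if deficient:
        raise NotEnabledError(t, deficient)
    counts = list(m.counts)
    for (tt, p), w in net.pre.items():
        if tt == t:
            counts[net.place_index(p)] -= w
    for (tt, p), w in net.post.items():
        if tt == t:
            counts[net.place_index(p)] += w
    return Marking(counts)


def fire_sequence(
    net: PetriNetStructure, m0: Marking, seq: Sequence[str]
) -> Trace:
    """Fire a transition sequence, recording every intermediate marking.

    The first infeasible step aborts with :class:`NotEnabledError`
    carrying its index.
    """
    m0 = _check_marking(net, m0)
    steps: list[tuple[str, Marking]] = []
    m = m0
    for i, t in enumerate(seq):
        try:
            m = fire(net, m, t)
        except NotEnabledError as exc:
            raise NotEnabledError(t, exc.deficient_places, step_index=i) from None
        steps.append((t, m))
    return Trace(
        initial=m0,
        steps=tuple(steps),
        terminated_dead=is_dead(net, m),
    )


def random_run(
    net: PetriNetStructure, m0: Marking, max_steps: int, seed: int
) -> Trace:
    """Run the token game choosing uniformly among enabled transitions.

    Stops at a dead marking or after ``max_steps`` firings.  Identical
    ``(net, m0, max_steps, seed)`` inputs produce identical traces.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    m0 = _check_marking(net, m0)
    rng = random.Random(seed)
    steps: list[tuple[str, Marking]] = []
    m = m0
    for _ in range(max_steps):
        enabled = enabled_set(net, m)
        if not enabled:
            break
        t = rng.choice(enabled)
        m = fire(net, m, t)
        steps.append((t, m))
    return Trace(
        initial=m0,
        steps=tuple(steps),
        terminated_dead=is_dead(net, m),
        seed=seed,
    )


def is_dead(net: PetriNetStructure, m: Marking) -> bool:
    """True iff no transition is enabled at ``m``."""
    return not enabled_set(net, m)
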