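"""Built-in models and random-net generation.

The DANA net (Dopamine And Norepinephrine Analyze) is a small published
qualitative model of monoamine-hormone action in depression: 8 places
(hormone pools and symptom states), 6 transitions (physiological
events), 18 weight-1 arcs, and an initial marking with one token each on
Bradykinesia (P2), Norepinephrine (P6), and Dopamine (P7).

Note on the structure: transition T0 ("Low Norepinephrine Levels")
consumes a token from P2 ("Bradykinesia") in addition to P6 — surprising
biologically but unambiguous in the model's published matrices; it is
reproduced here exactly as defined.

:func:`random_ordinary_net` generates seeded random ordinary nets
(all arc weights 1) for property-based testing against brute-force
oracles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .bio_annotation import AnnotatedNet, annotate
from .errors import NetDefinitionError
from .pn_core import Marking, PetriNetStructure

__all__ = ["NetSpecRecord", "DANA_SPEC", "build_dana", "random_ordinary_net"]


@dataclass(frozen=True)
class NetSpecRecord:
    """Declarative net description: ordered elements plus an arc list.

    Arcs are (source, target, weight) with source/target on opposite
    sides of the place/transition bipartition.
    """

    places: tuple[str, ...]
    transitions: tuple[str, ...]
    arcs: tuple[tuple[str, str, int], ...]
    initial_marking: tuple[int, ...]

    def to_net(self) -> PetriNetStructure:
        pset, tset = set(self.places), set(self.transitions)
        pre: dict[tuple[str, str], int] = {}
        post: dict[tuple[str, str], int] = {}
        for src, dst, w in self.arcs:
            if src in pset and dst in tset:
                pre[(dst, src)] = w
            elif src in tset and dst in pset:
                post[(src, dst)] = w
            else:
                raise NetDefinitionError(
                    f"arc ({src!r}, {dst!r}) must connect a place and a transition"
                )
        return PetriNetStructure(self.places, self.transitions, pre, post)


#: Frozen structural record of the DANA model.  The arc list is the
#: row-major decoding of the model's published 6×8 input/output matrices
#: (rows T0..T5, columns P0..P7); unit tests re-derive it from the
#: verbatim digit strings.
DANA_SPEC = NetSpecRecord(
    places=("P0", "P1", "P2", "P3", "P4", "P5", "P6", "P7"),
    transitions=("T0", "T1", "T2", "T3", "T4", "T5"),
    arcs=(
        # T0: low norepinephrine
        ("P2", "T0", 1),
        ("P6", "T0", 1),
        ("T0", "P0", 1),
        ("T0", "P1", 1),
        # T1: decreased willpower
        ("P0", "T1", 1),
        ("T1", "P3", 1),
        # T2: low dopamine
        ("P1", "T2", 1),
        ("P7", "T2", 1),
        ("T2", "P4", 1),
        # T3: psychomotor block
        ("P0", "T3", 1),
        ("P1", "T3", 1),
        ("T3", "P2", 1),
        # T4: feeling down
        ("P3", "T4", 1),
        ("P4", "T4", 1),
        ("T4", "P2", 1),
        ("T4", "P5", 1),
        # T5: thinking slow
        ("P2", "T5", 1),
        ("T5", "P5", 1),
    ),
    initial_marking=(0, 0, 1, 0, 0, 0, 1, 1),
)

DANA_PLACE_LABELS = {
    "P0": "Weakened Energy",
    "P1": "Cognitive Decline",
    "P2": "Bradykinesia",
    "P3": "intellectual disability",
    "P4": "Anhedonia",
    "P5": "Blocking Depression",
    "P6": "Norepinephrine",
    "P7": "Dopamine",
}

DANA_TRANSITION_LABELS = {
    "T0": "Low Norepinephrine Levels",
    "T1": "Decreased Willpower",
    "T2": "Low Dopamine Levels",
    "T3": "Psychomotor Block",
    "T4": "Feeling Down",
    "T5": "Thinking Slow",
}


def build_dana() -> AnnotatedNet:
    """Construct the annotated DANA model.

    Every call returns an equivalent immutable net; structure, labels
    and initial marking are frozen in :data:`DANA_SPEC`.
    """
    return annotate(
        DANA_SPEC.to_net(),
        place_labels=DANA_PLACE_LABELS,
        transition_labels=DANA_TRANSITION_LABELS,
        initial=Marking(DANA_SPEC.initial_marking),
    )


def random_ordinary_net(
    n_places: int, n_transitions: int, arc_prob: float, seed: int
) -> PetriNetStructure:
    """Seeded random ordinary net (all arc weights 1).

    Each potential place→transition and transition→place arc is included
    independently with probability ``arc_prob``.  Deterministic for a
    fixed seed.
    """
    if n_places < 1 or n_transitions < 1:
        raise ValueError("need at least one place and one transition")
    if not 0.0 <= arc_prob <= 1.0:
        raise ValueError("arc_prob must be in [0, 1]")
    rng = random.Random(seed)
    places = tuple(f"p{i}" for i in range(n_places))
    transitions = tuple(f"t{i}" for i in range(n_transitions))
    pre = {}
    post = {}
    for t in transitions:
        for p in places:
            if rng.random() < arc_prob:
                pre[(t, p)] = 1
            if rng.random() < arc_prob:
                post[(t, p)] = 1
    return PetriNetStructure(places, transitions, pre, post)
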