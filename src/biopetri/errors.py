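"""Exception hierarchy shared by all biopetri modules."""


class PetriNetError(Exception):
    """Base class for all biopetri errors."""


class NetDefinitionError(PetriNetError):
    """Structural constraint of a net definition violated."""


class UnknownIdentifierError(PetriNetError):
    """A place or transition identifier is not declared in the net."""


class NotEnabledError(PetriNetError):
    """A transition was fired while disabled.

    Attributes
    ----------
    transition : str
        Identifier of the disabled transition.
    deficient_places : tuple of str
        Places whose token count is below the required arc weight.
    step_index : int or None
        Position within a sequence, when raised from sequence execution.
    """

    def __init__(self, transition, deficient_places, step_index=None):
        self.transition = transition
        self.deficient_places = tuple(deficient_places)
        self.step_index = step_index
        where = f" at step {step_index}" if step_index is not None else ""
        super().__init__(
            f"transition {transition!r} is not enabled{where}: "
            f"insufficient tokens in {', '.join(self.deficient_places)}"
        )


class DimensionError(PetriNetError):
    """A vector or matrix has the wrong length/shape for the net."""


class KindError(PetriNetError):
    """An S-kind operation received a T-kind invariant or vice versa."""


class EnumerationSizeError(PetriNetError):
    """Brute-force enumeration would exceed its safety guard."""


class CompletenessError(PetriNetError):
    """An operation requiring a complete reachability graph got a truncated one."""


class FormatError(PetriNetError):
    """A file being read does not conform to the expected format."""
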