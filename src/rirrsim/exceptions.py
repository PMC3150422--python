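"""Exception hierarchy for rirrsim."""


class RirrsimError(Exception):
    """Base class for all rirrsim errors."""


class ParameterError(RirrsimError, ValueError):
    """An input parameter violates a precondition."""


class DomainError(RirrsimError, ValueError):
    """A query point or value lies outside the valid domain."""


class CapacityError(RirrsimError, RuntimeError):
    """A randomized placement could not be completed within the attempt budget."""


class FitError(RirrsimError, RuntimeError):
    """A regression could not be fit (rank-deficient or underdetermined design)."""


class LifetimeError(RirrsimError, ZeroDivisionError):
    """A messenger has no decay channel, so its lifetime is infinite."""
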