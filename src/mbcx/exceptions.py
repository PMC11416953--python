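"""Package-wide exception types.

Failure modes are loud by design: representational saturation, configuration
mismatches and capacity overflows raise rather than silently clip or evict.
"""


class MbcxError(Exception):
    """Base class for all package errors."""


class SaturationError(MbcxError):
    """A rate-coded quantity exceeded its representable range."""


class ConfigurationError(MbcxError):
    """Inconsistent or invalid configuration (column counts, policy params...)."""


class CapacityError(MbcxError):
    """A fixed-capacity store (vector memories, MBON budget) would overflow."""


class ValenceError(MbcxError):
    """A valence-split quantity (reward, DAN rate) was given a negative value."""


class CollisionError(MbcxError):
    """The agent pose intersects a solid world object."""


class GenerationError(MbcxError):
    """Random world generation failed to satisfy placement constraints."""


class EmptyTraceError(MbcxError):
    """A temporal-difference computation was requested before the one-step
    activity trace was primed (first transition of an episode)."""
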