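"""Exception hierarchy.

Everything raised deliberately by :mod:`arbordyn` derives from
:class:`ArbordynError`, so callers can catch pipeline errors without
swallowing programming mistakes.
"""


class ArbordynError(Exception):
    """Base class for all arbordyn errors."""


class SWCParseError(ArbordynError):
    """A line of an SWC file could not be parsed (message names the line)."""


class SkeletonStructureError(ArbordynError):
    """A skeleton violates structural invariants (dangling parent, multiple
    roots, cycle, disconnected forest, negative radius)."""


class ManifestError(ArbordynError):
    """A series manifest is inconsistent (non-monotonic times, unflagged
    missing file, unknown columns)."""


class DegeneratePointError(ArbordynError):
    """A point projects onto the sector-frame origin; its direction is
    undefined. The caller decides how to handle it (the soma is normally
    excluded upstream)."""


class SeriesTooShortError(ArbordynError):
    """An operation requires more frames than the series provides."""


class TrackContractError(ArbordynError):
    """A branch track violates the tracker contract (non-contiguous
    presence mask)."""


class InsufficientDataError(ArbordynError):
    """Not enough observations for a statistic or summary."""
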