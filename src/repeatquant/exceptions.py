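"""Exception hierarchy.

All package-specific failures derive from :class:`RepeatQuantError` so callers
can catch one base class; most also derive from ``ValueError`` because they
signal invalid inputs.
"""


class RepeatQuantError(Exception):
    """Base class for all repeatquant errors."""


class GridMismatchError(RepeatQuantError, ValueError):
    """Volume and mask (or two volumes) do not share shape and spacing."""


class EmptyMaskError(RepeatQuantError, ValueError):
    """A metric was requested over a mask with no voxels set."""


class ValueKindError(RepeatQuantError, ValueError):
    """Operation applied to a volume of an incompatible value kind."""


class OutOfDomainError(RepeatQuantError, ValueError):
    """Physiologic formula evaluated outside its valid domain."""


class InsufficientOverlapError(RepeatQuantError, ValueError):
    """Two acquisition windows do not overlap long enough for the frame."""
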