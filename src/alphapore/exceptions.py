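"""Exception hierarchy for alphapore."""


class AlphaporeError(Exception):
    """Base class for all alphapore errors."""


class FormatError(AlphaporeError):
    """An input file could not be parsed."""


class DegenerateInputError(AlphaporeError):
    """Input geometry is too degenerate to triangulate (e.g. < 4 atoms,
    coplanar centers)."""


class ParameterError(AlphaporeError):
    """A user-supplied parameter is out of its valid range."""


class NoChannelError(AlphaporeError):
    """No channel/pore exists between the requested endpoints."""


class DegeneratePathError(AlphaporeError):
    """A channel centerline is too short or self-coincident to process."""


class OutOfBoundsError(AlphaporeError):
    """A query point lies outside the domain of a sampled grid."""
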