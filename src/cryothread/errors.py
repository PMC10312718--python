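"""Exception hierarchy for the toolkit."""


class CryoThreadError(Exception):
    """Base class for all toolkit errors."""


class MRCFormatError(CryoThreadError):
    """File is not a readable MRC2014 volume (truncated, malformed header)."""


class UnsupportedModeError(MRCFormatError):
    """MRC mode code outside the supported set {0, 1, 2, 4, 6, 12}."""


class DimensionError(CryoThreadError):
    """A grid axis is degenerate or otherwise unusable for the operation."""


class OutOfBoundsError(CryoThreadError):
    """A grid index falls outside the map bounds.

    Carries the offending axis name in :attr:`axis`.
    """

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis


class EmptyModelError(CryoThreadError):
    """No candidate states survive selection; an HMM cannot be built."""


class PartialThreadError(CryoThreadError):
    """Threading could not place the full sequence.

    :attr:`prefix` holds the longest backbone prefix that was achievable
    (list of placed states), :attr:`n_placed` its length.
    """

    def __init__(self, message: str, prefix=None):
        super().__init__(message)
        self.prefix = prefix or []
        self.n_placed = len(self.prefix)


class GenerationError(CryoThreadError):
    """The synthetic backbone walk failed to place a residue."""
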