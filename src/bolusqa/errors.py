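"""Exception hierarchy.

Every error raised by the library derives from :class:`BolusQAError` so
callers (and the CLI) can catch one type at the pipeline boundary.
"""


class BolusQAError(Exception):
    """Base class for all library errors."""


class ValidationError(BolusQAError, ValueError):
    """A spec/parameter object violates one of its invariants.

    The message names the offending field.
    """


class AlignmentError(BolusQAError):
    """Two volumes that must share a grid (shape, spacing, origin) do not."""


class EmptyBodyError(BolusQAError):
    """No voxel above the HU threshold — nothing to segment."""


class EmptyBolusError(BolusQAError):
    """The marked area does not intersect the body surface."""


class EmptyStructureError(BolusQAError):
    """A DVH or report was requested for an empty mask."""


class ConfigurationError(BolusQAError):
    """A required configuration value (e.g. prescription dose) is missing."""


class CoverageError(BolusQAError):
    """All air-gap sample rays missed the bolus surface."""


class MeasurementError(BolusQAError):
    """Film reference readings are physically inconsistent."""


class STLFormatError(BolusQAError):
    """Unreadable or truncated STL file.

    ``byte_offset`` is the position at which parsing failed.
    """

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


class FixtureError(BolusQAError):
    """A packaged reference-table fixture is missing or malformed."""
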