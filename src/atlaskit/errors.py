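"""Exception hierarchy shared across the toolkit.

Every error raised by the library derives from :class:`AtlasKitError` so
callers (and the CLI) can map failures to exit codes without matching on
message text.
"""


class AtlasKitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(AtlasKitError):
    """A file exists but its content is not in a recognized/valid format."""


class ValidationError(AtlasKitError):
    """An argument violates a documented precondition."""


class BoundsError(AtlasKitError, IndexError):
    """An index (voxel, slice, cart position) is outside its valid range."""


class StructureError(AtlasKitError):
    """A hierarchy or bundle is internally inconsistent (cycles, orphans)."""


class ConfigurationError(AtlasKitError):
    """A configuration value is unusable (unknown key, budget too small)."""


class StateError(AtlasKitError):
    """An operation requires state the object does not have."""


class DegeneracyError(AtlasKitError):
    """Input geometry is degenerate (coincident/collinear landmarks)."""


class BackendError(AtlasKitError):
    """A pluggable backend failed or is misregistered."""
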