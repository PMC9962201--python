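"""Exception hierarchy shared across the pipeline."""


class ArcP450Error(Exception):
    """Base class for all package-specific errors."""


class FormatError(ArcP450Error):
    """A file violates its format contract (malformed header, bad field...)."""


class CoordinateError(FormatError):
    """Genomic coordinates violate the 1-based inclusive contract."""


class DuplicateIdError(ArcP450Error):
    """An identifier that must be unique occurs more than once."""


class ConfigurationError(ArcP450Error):
    """A parameter set or rule table is internally inconsistent or missing."""


class LinkageError(ArcP450Error):
    """A cross-table reference (protein -> feature -> replicon) cannot be resolved."""


class GenerationError(ArcP450Error):
    """The synthetic-data generator cannot satisfy the requested constraints."""


class NamingError(ArcP450Error):
    """A generated label collides with an existing reference label."""
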