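"""Exception hierarchy for citegate.

All package-raised errors derive from :class:`CitegateError` so callers (and
the CLI) can catch one base class and convert to an exit status.
"""


class CitegateError(Exception):
    """Base class for all citegate errors."""


class FormatError(CitegateError):
    """An input file is malformed or a required member file is missing."""


class ValidationError(CitegateError):
    """Data violates a container/gate/spec invariant."""


class FeatureNotFoundError(CitegateError):
    """A requested assay or feature does not resolve in the container."""


class ChainingError(CitegateError):
    """A gate's input barcodes do not match the chain's current output set."""


class SchemaVersionError(CitegateError):
    """A scheme file declares an unsupported schema version."""


class SchemaError(CitegateError):
    """A scheme file is missing a required key or has a malformed value."""
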