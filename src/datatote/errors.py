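"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`DatatoteError`
carrying a single-line message suitable for printing on stderr.
"""


class DatatoteError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DatatoteError):
    """Input violates a format rule (dataset name, relpath, overlay key...)."""


class StateError(DatatoteError):
    """Operation not permitted in the dataset's current lifecycle state."""


class NotFoundError(DatatoteError):
    """A dataset, item or named artefact does not exist."""


class ProtoDatasetError(DatatoteError):
    """A frozen dataset was expected but the URI points at a proto dataset."""


class CollisionError(DatatoteError):
    """Destination already holds a dataset with the same identity."""


class ConfigurationError(DatatoteError):
    """Unknown hash algorithm, unregistered URI scheme, bad configuration."""


class UnsupportedSchemeError(ConfigurationError):
    """URI scheme has no registered storage broker in this build."""
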