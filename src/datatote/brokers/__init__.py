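"""Storage brokers and the scheme registry."""

from __future__ import annotations

from ..config import Config
from ..errors import UnsupportedSchemeError
from ..uri import DatasetURI, parse_uri
from .base import ItemProperties, StorageBroker
from .disk import DiskStorageBroker
from .mock import MockObjectStorageBroker

__all__ = [
    "DiskStorageBroker",
    "ItemProperties",
    "MockObjectStorageBroker",
    "StorageBroker",
    "broker_class_for_scheme",
    "broker_for",
    "register_broker",
]

_REGISTRY: dict[str, type[StorageBroker]] = {}

# Schemes a networked build would serve; named so the error message can
# distinguish "not supported in this build" from a typo.
_KNOWN_UNSUPPORTED = ("s3", "azure", "irods", "http", "https")


def register_broker(cls: type[StorageBroker]) -> type[StorageBroker]:
    """Register a broker class under its scheme.  Usable as a decorator,
    so third-party brokers plug in without touching existing code."""
    _REGISTRY[cls.scheme] = cls
    return cls


register_broker(DiskStorageBroker)
register_broker(MockObjectStorageBroker)


def broker_class_for_scheme(scheme: str) -> type[StorageBroker]:
    try:
        return _REGISTRY[scheme]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        if scheme in _KNOWN_UNSUPPORTED:
            raise UnsupportedSchemeError(
                "Scheme {!r} is not supported in this build; "
                "registered schemes: {}".format(scheme, known)
            ) from None
        raise UnsupportedSchemeError(
            "No storage broker registered for scheme {!r}; "
            "registered schemes: {}".format(scheme, known)
        ) from None


def broker_for(uri: str | DatasetURI, config: Config | None = None) -> StorageBroker:
    """Instantiate the broker serving *uri*."""
    if isinstance(uri, str):
        uri = parse_uri(uri)
    return broker_class_for_scheme(uri.scheme)(uri, config)
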