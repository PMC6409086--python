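"""Item identifiers, content hashing and human-readable sizes.

These are the numeric primitives of the dataset format:

* An item *identifier* is the SHA-1 hex digest of the UTF-8 encoding of the
  item's relative path.  It depends only on the relpath, never on content or
  storage medium, so the same logical item has the same identifier on disk
  and in an object store.
* Content *fixity* is established with a checksum of the item's bytes.  The
  default algorithm is MD5, recorded in the manifest under the label
  ``md5sum_hexdigest``; the manifest label is authoritative when reading, so
  datasets written with a different registered algorithm verify correctly.
* Sizes are rendered with binary prefixes (1 KiB = 1024 B) and one decimal
  place, e.g. ``3.6GiB``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import BinaryIO, Callable

from .errors import ConfigurationError

__all__ = [
    "ContentHash",
    "DEFAULT_HASH_NAME",
    "format_size",
    "generate_identifier",
    "hash_file_content",
    "hash_stream",
    "registered_hash_names",
]

#: Manifest label of the default content-hash algorithm.
DEFAULT_HASH_NAME = "md5sum_hexdigest"

# Registry mapping manifest hash-function labels to hashlib constructors.
# Extensible: labels follow the "<tool>_hexdigest" naming convention.
_HASHERS: dict[str, Callable] = {
    "md5sum_hexdigest": hashlib.md5,
    "sha1sum_hexdigest": hashlib.sha1,
    "sha256sum_hexdigest": hashlib.sha256,
}

#: Chunk size for streaming file hashing.  Fixed so that memory use is
#: independent of file size.
_CHUNK_SIZE = 64 * 1024


@dataclass(frozen=True)
class ContentHash:
    """A content digest together with the algorithm that produced it."""

    algorithm_name: str
    digest: str


def registered_hash_names() -> list[str]:
    """Return the manifest labels of all registered hash algorithms."""
    return sorted(_HASHERS)


def generate_identifier(relpath: str) -> str:
    """Return the item identifier for a relative path.

    The identifier is the SHA-1 hex digest of the UTF-8 encoding of
    *relpath*: 40 lowercase hexadecimal characters.  This is a pure
    function of the text; no filesystem access takes place.

    >>> generate_identifier("ERR022075_2.fastq.gz")
    '8bda245a8cd526673aab775f90206c8b67d196af'
    """
    return hashlib.sha1(relpath.encode("utf-8")).hexdigest()


def _hasher_for(algorithm: str):
    try:
        return _HASHERS[algorithm]
    except KeyError:
        raise ConfigurationError(
            "Unknown hash algorithm {!r}; registered algorithms: {}".format(
                algorithm, ", ".join(registered_hash_names())
            )
        ) from None


def hash_stream(stream: BinaryIO, algorithm: str = DEFAULT_HASH_NAME) -> ContentHash:
    """Digest a binary stream in fixed-size chunks."""
    hasher = _hasher_for(algorithm)()
    for chunk in iter(lambda: stream.read(_CHUNK_SIZE), b""):
        hasher.update(chunk)
    return ContentHash(algorithm_name=algorithm, digest=hasher.hexdigest())


def hash_file_content(path: str, algorithm: str = DEFAULT_HASH_NAME) -> ContentHash:
    """Return the content hash of the file at *path*.

    The file is read in 64 KiB chunks so arbitrarily large items are hashed
    in constant memory.  An unreadable file raises the underlying
    :class:`OSError`, which names the path; an unregistered *algorithm*
    raises :class:`~datatote.errors.ConfigurationError` listing the
    registered names.
    """
    _hasher_for(algorithm)  # fail on bad algorithm before touching the file
    with open(path, "rb") as fh:
        return hash_stream(fh, algorithm)


_SIZE_UNITS = ("B", "KiB", "MiB", "GiB", "TiB")


def format_size(n_bytes: int) -> str:
    """Render a byte count with binary prefixes and one decimal place.

    The largest unit with value >= 1 is chosen (plain bytes below 1024),
    and the value is rounded half-up to one decimal — so 3858445043 bytes
    (~3.593 GiB) renders as ``'3.6GiB'``.  There is no space between the
    number and the unit.
    """
    if n_bytes < 0:
        raise ValueError("n_bytes must be non-negative, got {}".format(n_bytes))
    power = 0
    while power < len(_SIZE_UNITS) - 1 and n_bytes >= 1024 ** (power + 1):
        power += 1
    value = Decimal(n_bytes) / Decimal(1024**power)
    rounded = value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return "{}{}".format(rounded, _SIZE_UNITS[power])
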