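"""Dataset URIs.

A dataset location is written ``scheme://location``.  A bare path (no
scheme) refers to the local filesystem and normalizes to an absolute
``file://`` URI; normalization is idempotent.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

from .errors import ValidationError

_SCHEME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9+.-]*)://(.*)$")


@dataclass(frozen=True)
class DatasetURI:
    scheme: str
    location: str

    @property
    def normalized_text(self) -> str:
        return "{}://{}".format(self.scheme, self.location)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.normalized_text


def parse_uri(text: str) -> DatasetURI:
    """Parse *text* into a :class:`DatasetURI`.

    Relative paths are resolved against the current working directory and
    given the ``file`` scheme.  Unknown schemes are preserved so the broker
    registry can reject them with a helpful message.
    """
    if not text:
        raise ValidationError("URI must be non-empty text")
    match = _SCHEME_RE.match(text)
    if match is None:
        return DatasetURI(scheme="file", location=os.path.abspath(text))
    scheme, location = match.group(1).lower(), match.group(2)
    if scheme in ("file", "mock"):
        location = os.path.normpath(location) if location else "/"
    return DatasetURI(scheme=scheme, location=location)
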