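"""The storage-broker contract.

A storage broker maps the dataset abstraction onto a concrete medium.  All
dataset-level reads and writes flow through this contract; the core model
never touches a directory tree, object key or network endpoint directly.
A broker that satisfies the contract therefore makes every dataset
operation — create, add, freeze, load, verify, copy, fetch — behave
identically to every other broker.

Named text artefacts
--------------------
Brokers store four named text artefacts per dataset, addressed by logical
key: ``admin`` (administrative record, JSON), ``manifest`` (structural
metadata, JSON), ``readme`` (descriptive metadata, YAML, byte-preserved)
and ``structure`` (a description of the broker's own layout, JSON).
Overlays are stored separately, one JSON document per overlay name.

Items
-----
Items are addressed by their relative path while the dataset is under
construction, and by (identifier, relpath) afterwards.  How the bytes are
laid out — a directory tree mirroring relpaths, or a flat identifier-keyed
object space — is the broker's business alone.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import ClassVar, Iterator

from ..config import Config, load_config
from ..uri import DatasetURI

ARTIFACT_KEYS = ("admin", "manifest", "readme", "structure")


@dataclass(frozen=True)
class ItemProperties:
    """Size and timestamp of a stored item, as reported by the medium."""

    size_in_bytes: int
    utc_timestamp: float


class StorageBroker(abc.ABC):
    """Behavioral contract for a concrete storage medium."""

    #: URI scheme this broker serves, e.g. ``"file"``.
    scheme: ClassVar[str]

    def __init__(self, uri: DatasetURI, config: Config | None = None):
        self.uri = uri
        self.config = config or load_config()

    # -- dataset addressing -------------------------------------------------

    @classmethod
    @abc.abstractmethod
    def dataset_uri(cls, base_uri: DatasetURI, name: str, uuid: str) -> DatasetURI:
        """The URI a dataset with *name* and *uuid* gets under *base_uri*."""

    @classmethod
    @abc.abstractmethod
    def list_dataset_uris(cls, base_uri: DatasetURI) -> list[DatasetURI]:
        """URIs of all datasets directly under *base_uri*."""

    # -- structure ----------------------------------------------------------

    @abc.abstractmethod
    def exists(self) -> bool:
        """True if anything at all occupies this dataset's location."""

    @abc.abstractmethod
    def create_structure(self) -> None:
        """Initialize the on-medium structure for a new dataset."""

    # -- named text artefacts ----------------------------------------------

    @abc.abstractmethod
    def put_artifact(self, key: str, text: str) -> None: ...

    @abc.abstractmethod
    def get_artifact(self, key: str) -> str: ...

    @abc.abstractmethod
    def has_artifact(self, key: str) -> bool: ...

    # -- overlays -----------------------------------------------------------

    @abc.abstractmethod
    def put_overlay_text(self, name: str, text: str) -> None: ...

    @abc.abstractmethod
    def get_overlay_text(self, name: str) -> str: ...

    @abc.abstractmethod
    def list_overlay_names(self) -> list[str]: ...

    # -- items --------------------------------------------------------------

    @abc.abstractmethod
    def put_item(self, source_path: str, relpath: str) -> None:
        """Store the bytes of the local file *source_path* under *relpath*,
        preserving the source's modification time."""

    @abc.abstractmethod
    def iter_item_relpaths(self) -> Iterator[str]:
        """Relative paths of every item currently stored."""

    @abc.abstractmethod
    def item_exists(self, relpath: str) -> bool: ...

    @abc.abstractmethod
    def item_properties(self, relpath: str) -> ItemProperties:
        """Size in bytes and UTC modification timestamp of a stored item."""

    @abc.abstractmethod
    def stored_item_path(self, relpath: str) -> str:
        """A local path to the stored bytes, for hashing during freeze and
        verification.  Brokers for non-local media materialize here."""

    @abc.abstractmethod
    def stored_identifiers(self) -> set[str]:
        """Identifiers of every item present on the medium (for detecting
        items that are not accounted for by the manifest)."""

    @abc.abstractmethod
    def fetch_item(self, identifier: str, relpath: str) -> str:
        """An absolute local path where the item's content can be read.

        For non-local media the item is first materialized into the cache
        directory; a second fetch reuses the cached copy.
        """
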