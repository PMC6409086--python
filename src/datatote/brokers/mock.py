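"""Local object-store broker (``mock://`` scheme).

Emulates how a dataset lives in object storage, using a local directory as
the store: datasets are addressed by UUID rather than by name, item bytes
are stored flat under identifier-derived keys with no relpath-derived
directory tree, and reading an item's content goes through a local cache
directory.  This exercises every code path a networked object-store broker
needs — identifier-keyed blobs, flat metadata keys, fetch-time
materialization — without any network.

Store layout for ``mock://<store>/<uuid>``::

    <store>/<uuid>/
        admin, manifest, readme, structure    flat metadata key files
        overlay.<name>                        one flat key per overlay
        handle.<identifier>                   the item's relpath (text)
        data/<identifier>                     the item's bytes
"""

from __future__ import annotations

import os
import shutil
from typing import Iterator

from ..errors import NotFoundError
from ..hashing import generate_identifier
from ..uri import DatasetURI
from .base import ItemProperties, StorageBroker

_HANDLE_PREFIX = "handle."
_OVERLAY_PREFIX = "overlay."


class MockObjectStorageBroker(StorageBroker):
    """Object-storage semantics backed by a local directory."""

    scheme = "mock"

    def __init__(self, uri, config=None):
        super().__init__(uri, config)
        self._root = uri.location  # <store>/<uuid>
        self._uuid = os.path.basename(uri.location)

    @classmethod
    def dataset_uri(cls, base_uri: DatasetURI, name: str, uuid: str) -> DatasetURI:
        return DatasetURI(scheme="mock", location=os.path.join(base_uri.location, uuid))

    @classmethod
    def list_dataset_uris(cls, base_uri: DatasetURI) -> list[DatasetURI]:
        base = base_uri.location
        if not os.path.isdir(base):
            return []
        uris = []
        for entry in sorted(os.listdir(base)):
            candidate = os.path.join(base, entry)
            if os.path.isfile(os.path.join(candidate, "admin")):
                uris.append(DatasetURI(scheme="mock", location=candidate))
        return uris

    def exists(self) -> bool:
        return os.path.exists(self._root)

    def create_structure(self) -> None:
        os.makedirs(os.path.join(self._root, "data"))
        self._put_key("readme", "")
        import json

        structure = {
            "addressing": "uuid",
            "item_keys": "data/<identifier>",
            "metadata_keys": "flat",
            "storage_broker": type(self).__name__,
        }
        self._put_key("structure", json.dumps(structure, indent=2, sort_keys=True) + "\n")

    # -- flat keys ----------------------------------------------------------

    def _key_path(self, key: str) -> str:
        return os.path.join(self._root, key)

    def _put_key(self, key: str, text: str) -> None:
        with open(self._key_path(key), "w", encoding="utf-8", newline="") as fh:
            fh.write(text)

    def _get_key(self, key: str) -> str:
        try:
            with open(self._key_path(key), "r", encoding="utf-8", newline="") as fh:
                return fh.read()
        except FileNotFoundError:
            raise NotFoundError(
                "No such key {!r} at {}".format(key, self.uri.normalized_text)
            ) from None

    def put_artifact(self, key: str, text: str) -> None:
        self._put_key(key, text)

    def get_artifact(self, key: str) -> str:
        return self._get_key(key)

    def has_artifact(self, key: str) -> bool:
        return os.path.isfile(self._key_path(key))

    # -- overlays -----------------------------------------------------------

    def put_overlay_text(self, name: str, text: str) -> None:
        self._put_key(_OVERLAY_PREFIX + name, text)

    def get_overlay_text(self, name: str) -> str:
        try:
            return self._get_key(_OVERLAY_PREFIX + name)
        except NotFoundError:
            raise NotFoundError("No overlay named {!r}".format(name)) from None

    def list_overlay_names(self) -> list[str]:
        if not os.path.isdir(self._root):
            return []
        return sorted(
            entry[len(_OVERLAY_PREFIX) :]
            for entry in os.listdir(self._root)
            if entry.startswith(_OVERLAY_PREFIX)
        )

    # -- items --------------------------------------------------------------

    def _blob_path(self, identifier: str) -> str:
        return os.path.join(self._root, "data", identifier)

    def put_item(self, source_path: str, relpath: str) -> None:
        identifier = generate_identifier(relpath)
        shutil.copy2(source_path, self._blob_path(identifier))
        self._put_key(_HANDLE_PREFIX + identifier, relpath)

    def iter_item_relpaths(self) -> Iterator[str]:
        for entry in sorted(os.listdir(self._root)):
            if entry.startswith(_HANDLE_PREFIX):
                yield self._get_key(entry)

    def item_exists(self, relpath: str) -> bool:
        return os.path.isfile(self._blob_path(generate_identifier(relpath)))

    def item_properties(self, relpath: str) -> ItemProperties:
        stat = os.stat(self._blob_path(generate_identifier(relpath)))
        return ItemProperties(size_in_bytes=stat.st_size, utc_timestamp=stat.st_mtime)

    def stored_item_path(self, relpath: str) -> str:
        return self._blob_path(generate_identifier(relpath))

    def stored_identifiers(self) -> set[str]:
        data_dir = os.path.join(self._root, "data")
        if not os.path.isdir(data_dir):
            return set()
        return set(os.listdir(data_dir))

    def fetch_item(self, identifier: str, relpath: str) -> str:
        cache_dir = os.path.join(self.config.cache_directory, self._uuid)
        cached = os.path.join(cache_dir, identifier)
        if not os.path.isfile(cached):
            os.makedirs(cache_dir, exist_ok=True)
            partial = cached + ".part"
            shutil.copy2(self._blob_path(identifier), partial)
            os.replace(partial, cached)
        return os.path.abspath(cached)
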