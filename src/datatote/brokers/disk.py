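"""Filesystem storage broker.

On disk a dataset is a directory::

    <name>/
        README.yml              descriptive metadata (user-supplied YAML)
        data/                   the items, at their relative paths
        .dtool/
            dtool               administrative record (JSON)
            manifest.json       structural metadata (written at freeze)
            structure.json      what each file in this layout is
            README.txt          plain-text note for people who stumble in
            overlays/           per-item descriptive metadata (JSON each)

The ``.dtool/`` names are format constants: datasets written here are
readable by any tool that understands this widely used on-disk layout.
A directory is recognised as a dataset by the presence of ``.dtool/dtool``;
that file is always written last, so an interrupted copy is never mistaken
for a complete dataset.
"""

from __future__ import annotations

import os
import shutil
from typing import Iterator

from ..errors import NotFoundError
from ..hashing import generate_identifier
from ..uri import DatasetURI
from .base import ItemProperties, StorageBroker

ADMIN_RELPATH = ".dtool/dtool"
MANIFEST_RELPATH = ".dtool/manifest.json"
STRUCTURE_RELPATH = ".dtool/structure.json"
NOTE_RELPATH = ".dtool/README.txt"
README_RELPATH = "README.yml"
DATA_DIRNAME = "data"
OVERLAYS_DIRNAME = ".dtool/overlays"

_ARTIFACT_RELPATHS = {
    "admin": ADMIN_RELPATH,
    "manifest": MANIFEST_RELPATH,
    "readme": README_RELPATH,
    "structure": STRUCTURE_RELPATH,
}

STRUCTURE_NOTE = """\
This directory is a dataset: a packaged collection of data files together
with administrative, structural and descriptive metadata.

The files under .dtool/ are managed by software and must not be edited by
hand; doing so will break the integrity checks on the dataset.  The data
files live under data/ and the human-readable description of the dataset
is in README.yml.  See .dtool/structure.json for a machine-readable map
of this layout.
"""


class DiskStorageBroker(StorageBroker):
    """Stores a dataset as a plain directory tree."""

    scheme = "file"

    def __init__(self, uri, config=None):
        super().__init__(uri, config)
        self._root = uri.location

    # -- dataset addressing -------------------------------------------------

    @classmethod
    def dataset_uri(cls, base_uri: DatasetURI, name: str, uuid: str) -> DatasetURI:
        return DatasetURI(scheme="file", location=os.path.join(base_uri.location, name))

    @classmethod
    def list_dataset_uris(cls, base_uri: DatasetURI) -> list[DatasetURI]:
        base = base_uri.location
        if not os.path.isdir(base):
            return []
        uris = []
        for entry in sorted(os.listdir(base)):
            candidate = os.path.join(base, entry)
            if os.path.isfile(os.path.join(candidate, ADMIN_RELPATH)):
                uris.append(DatasetURI(scheme="file", location=candidate))
        return uris

    # -- structure ----------------------------------------------------------

    def exists(self) -> bool:
        return os.path.exists(self._root)

    def create_structure(self) -> None:
        os.makedirs(os.path.join(self._root, DATA_DIRNAME))
        os.makedirs(os.path.join(self._root, OVERLAYS_DIRNAME))
        self._write_text(NOTE_RELPATH, STRUCTURE_NOTE)
        self._write_text(README_RELPATH, "")
        structure = {
            "admin_record": ADMIN_RELPATH,
            "data_directory": DATA_DIRNAME,
            "descriptive_metadata": README_RELPATH,
            "manifest": MANIFEST_RELPATH,
            "overlays_directory": OVERLAYS_DIRNAME,
            "storage_broker": type(self).__name__,
            "structure_note": NOTE_RELPATH,
        }
        import json

        self._write_text(
            STRUCTURE_RELPATH, json.dumps(structure, indent=2, sort_keys=True) + "\n"
        )

    # -- helpers ------------------------------------------------------------

    def _abspath(self, relpath: str) -> str:
        return os.path.join(self._root, *relpath.split("/"))

    def _write_text(self, relpath: str, text: str) -> None:
        path = self._abspath(relpath)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)

    def _read_text(self, relpath: str) -> str:
        path = self._abspath(relpath)
        try:
            with open(path, "r", encoding="utf-8", newline="") as fh:
                return fh.read()
        except FileNotFoundError:
            raise NotFoundError("No such artefact: {}".format(path)) from None

    # -- named text artefacts ----------------------------------------------

    def put_artifact(self, key: str, text: str) -> None:
        self._write_text(_ARTIFACT_RELPATHS[key], text)

    def get_artifact(self, key: str) -> str:
        return self._read_text(_ARTIFACT_RELPATHS[key])

    def has_artifact(self, key: str) -> bool:
        return os.path.isfile(self._abspath(_ARTIFACT_RELPATHS[key]))

    # -- overlays -----------------------------------------------------------

    def _overlay_path(self, name: str) -> str:
        return os.path.join(self._root, OVERLAYS_DIRNAME, name + ".json")

    def put_overlay_text(self, name: str, text: str) -> None:
        os.makedirs(os.path.join(self._root, OVERLAYS_DIRNAME), exist_ok=True)
        with open(self._overlay_path(name), "w", encoding="utf-8") as fh:
            fh.write(text)

    def get_overlay_text(self, name: str) -> str:
        try:
            with open(self._overlay_path(name), "r", encoding="utf-8") as fh:
                return fh.read()
        except FileNotFoundError:
            raise NotFoundError("No overlay named {!r}".format(name)) from None

    def list_overlay_names(self) -> list[str]:
        overlay_dir = os.path.join(self._root, OVERLAYS_DIRNAME)
        if not os.path.isdir(overlay_dir):
            return []
        return sorted(
            os.path.splitext(entry)[0]
            for entry in os.listdir(overlay_dir)
            if entry.endswith(".json")
        )

    # -- items --------------------------------------------------------------

    def _item_abspath(self, relpath: str) -> str:
        return os.path.join(self._root, DATA_DIRNAME, *relpath.split("/"))

    def put_item(self, source_path: str, relpath: str) -> None:
        dest = self._item_abspath(relpath)
        os.makedirs(os.path.dirname(dest), exist_ok=True)
        shutil.copy2(source_path, dest)

    def iter_item_relpaths(self) -> Iterator[str]:
        data_dir = os.path.join(self._root, DATA_DIRNAME)
        for dirpath, _dirnames, filenames in os.walk(data_dir):
            for filename in filenames:
                abspath = os.path.join(dirpath, filename)
                rel = os.path.relpath(abspath, data_dir)
                yield rel.replace(os.sep, "/")

    def item_exists(self, relpath: str) -> bool:
        return os.path.isfile(self._item_abspath(relpath))

    def item_properties(self, relpath: str) -> ItemProperties:
        stat = os.stat(self._item_abspath(relpath))
        return ItemProperties(size_in_bytes=stat.st_size, utc_timestamp=stat.st_mtime)

    def stored_item_path(self, relpath: str) -> str:
        return self._item_abspath(relpath)

    def stored_identifiers(self) -> set[str]:
        return {generate_identifier(rp) for rp in self.iter_item_relpaths()}

    def fetch_item(self, identifier: str, relpath: str) -> str:
        # Items are already local files; no cache step is needed.
        return self._item_abspath(relpath)
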