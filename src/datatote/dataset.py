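"""The dataset abstraction: proto-dataset lifecycle, freezing, manifests,
verification and copying — independent of any storage medium.

A *dataset* packages data files ("items") together with three kinds of
metadata:

* administrative — UUID, name, creator, lifecycle state, freeze time;
* structural — the manifest: for every item its relative path, size in
  bytes, content hash and modification timestamp, keyed by the item's
  identifier (SHA-1 of the relpath);
* descriptive — free-form YAML (the readme) plus per-item overlays.

A dataset starts life as a mutable *proto dataset* to which items are
added.  *Freezing* computes the manifest from the stored bytes (storage,
not the add-call history, is the source of truth), stamps the freeze time
and makes the dataset immutable.  From then on the manifest supports
fixity checking: ``verify`` compares what the medium holds against what
the manifest promises.
"""

from __future__ import annotations

import json
import re
import time
import uuid as uuid_module
from dataclasses import dataclass, field
from typing import Iterable

from .brokers import StorageBroker, broker_class_for_scheme, broker_for
from .config import Config, load_config
from .errors import (
    CollisionError,
    NotFoundError,
    ProtoDatasetError,
    StateError,
    ValidationError,
)
from .hashing import DEFAULT_HASH_NAME, format_size, generate_identifier, hash_file_content
from .uri import DatasetURI, parse_uri

__all__ = [
    "Dataset",
    "DatasetEntry",
    "ProtoDataset",
    "SummaryRecord",
    "VerifyReport",
    "copy_dataset",
    "create_proto_dataset",
    "list_datasets",
    "load_dataset",
    "load_proto_dataset",
    "summarize",
]

#: Version of the administrative-record format written by this package.
FORMAT_VERSION = "1.0"

#: Top-level version label written into manifests.  The key name is a
#: format constant shared with other tools that read this layout.
MANIFEST_VERSION = "3.7.0"

_NAME_RE = re.compile(r"^[A-Za-z0-9._-]+$")


def _json_text(obj) -> str:
    """Canonical JSON serialization: sorted keys, two-space indent."""
    return json.dumps(obj, indent=2, sort_keys=True) + "\n"


def validate_name(name: str) -> str:
    if not _NAME_RE.match(name or ""):
        raise ValidationError(
            "Invalid dataset name {!r}: use only letters, digits, '.', '-' "
            "and '_' (no whitespace)".format(name)
        )
    return name


def validate_relpath(relpath: str) -> str:
    if not relpath:
        raise ValidationError("Item relpath must be non-empty")
    if relpath.startswith("/"):
        raise ValidationError("Item relpath must be relative, got {!r}".format(relpath))
    if any(segment in (".", "..", "") for segment in relpath.split("/")):
        raise ValidationError(
            "Item relpath must not contain '.', '..' or empty segments: {!r}".format(relpath)
        )
    return relpath


# ---------------------------------------------------------------------------
# report / record types


@dataclass
class VerifyReport:
    """Outcome of a fixity check against the manifest."""

    missing: list[tuple[str, str]] = field(default_factory=list)
    unknown: list[str] = field(default_factory=list)
    altered_size: list[tuple[str, str]] = field(default_factory=list)
    altered_hash: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing or self.unknown or self.altered_size or self.altered_hash)


@dataclass(frozen=True)
class SummaryRecord:
    name: str
    uuid: str
    creator_username: str
    number_of_items: int
    total_size_in_bytes: int
    frozen_at: float

    @property
    def size_text(self) -> str:
        return format_size(self.total_size_in_bytes)


@dataclass(frozen=True)
class DatasetEntry:
    """One dataset found under a base URI."""

    name: str
    uri: str
    state: str


# ---------------------------------------------------------------------------
# handles


class _DatasetBase:
    def __init__(self, broker: StorageBroker, admin: dict):
        self._broker = broker
        self._admin = admin

    @property
    def broker(self) -> StorageBroker:
        return self._broker

    @property
    def uri(self) -> str:
        return self._broker.uri.normalized_text

    @property
    def uuid(self) -> str:
        return self._admin["uuid"]

    @property
    def name(self) -> str:
        return self._admin["name"]

    @property
    def state(self) -> str:
        return self._admin["state"]

    @property
    def creator_username(self) -> str:
        return self._admin["creator_username"]

    @property
    def admin_record(self) -> dict:
        return dict(self._admin)

    def get_readme(self) -> str:
        """The descriptive metadata, byte-for-byte as last written."""
        return self._broker.get_artifact("readme")

    def put_readme(self, text: str) -> None:
        """Store descriptive metadata verbatim.  Allowed in both lifecycle
        states: the readme is curatorial, not structural."""
        self._broker.put_artifact("readme", text)


class ProtoDataset(_DatasetBase):
    """A dataset under construction; items may be added until freeze."""

    def add_item(self, source_path: str, relpath: str | None = None) -> str:
        """Store a local file as an item and return its identifier.

        *relpath* defaults to the source's filename.  Re-adding an existing
        relpath replaces the previous content (last write wins); the
        identifier is unchanged because it depends only on the relpath.
        """
        if relpath is None:
            import os

            relpath = os.path.basename(source_path)
        validate_relpath(relpath)
        with open(source_path, "rb"):
            pass  # surface unreadable sources as an OSError naming the path
        self._broker.put_item(source_path, relpath)
        return generate_identifier(relpath)

    def freeze(self) -> "Dataset":
        """Compute the manifest from the stored items and make the dataset
        immutable.  Per item the manifest records relpath, size, content
        hash and the stored file's modification time."""
        items = {}
        for relpath in self._broker.iter_item_relpaths():
            identifier = generate_identifier(relpath)
            props = self._broker.item_properties(relpath)
            digest = hash_file_content(
                self._broker.stored_item_path(relpath), DEFAULT_HASH_NAME
            ).digest
            items[identifier] = {
                "hash": digest,
                "relpath": relpath,
                "size_in_bytes": props.size_in_bytes,
                "utc_timestamp": float(props.utc_timestamp),
            }
        manifest = {
            "dtoolcore_version": MANIFEST_VERSION,
            "hash_function": DEFAULT_HASH_NAME,
            "items": items,
        }
        self._broker.put_artifact("manifest", _json_text(manifest))
        self._admin["state"] = "frozen"
        self._admin["frozen_at"] = float(time.time())
        self._broker.put_artifact("admin", _json_text(self._admin))
        return Dataset(self._broker, self._admin)


class Dataset(_DatasetBase):
    """A frozen, immutable dataset."""

    def __init__(self, broker, admin):
        super().__init__(broker, admin)
        self._manifest: dict | None = None

    # -- structural metadata -------------------------------------------------

    @property
    def manifest(self) -> dict:
        if self._manifest is None:
            self._manifest = json.loads(self._broker.get_artifact("manifest"))
        return self._manifest

    @property
    def identifiers(self) -> list[str]:
        """Manifest identifiers in ascending lexicographic order."""
        return sorted(self.manifest["items"])

    def item_record(self, identifier: str) -> dict:
        try:
            return self.manifest["items"][identifier]
        except KeyError:
            raise NotFoundError(
                "No item with identifier {} in dataset {}".format(identifier, self.uri)
            ) from None

    def item_relpath(self, identifier: str) -> str:
        return self.item_record(identifier)["relpath"]

    def fetch_item(self, identifier: str) -> str:
        """An absolute local path where the item's bytes can be read."""
        relpath = self.item_relpath(identifier)
        return self._broker.fetch_item(identifier, relpath)

    # -- descriptive metadata ------------------------------------------------

    def list_overlay_names(self) -> list[str]:
        return self._broker.list_overlay_names()

    def get_overlay(self, name: str) -> dict:
        return json.loads(self._broker.get_overlay_text(name))

    def put_overlay(self, name: str, mapping: dict) -> None:
        from .metadata import validate_overlay  # local import avoids a cycle

        validate_overlay(name, mapping, set(self.manifest["items"]))
        self._broker.put_overlay_text(name, _json_text(mapping))

    # -- fixity ----------------------------------------------------------------

    def verify(self, full: bool = False) -> VerifyReport:
        """Check the medium against the manifest.

        The default check confirms that every manifest identifier is
        present with the recorded size; ``full`` additionally recomputes
        content hashes with the manifest's hash function.  Items present on
        storage but absent from the manifest are reported as unknown.
        Discrepancies are report content, never exceptions.
        """
        report = VerifyReport()
        algorithm = self.manifest["hash_function"]
        for identifier in self.identifiers:
            record = self.manifest["items"][identifier]
            relpath = record["relpath"]
            if not self._broker.item_exists(relpath):
                report.missing.append((identifier, relpath))
                continue
            props = self._broker.item_properties(relpath)
            if props.size_in_bytes != record["size_in_bytes"]:
                report.altered_size.append((identifier, relpath))
            if full:
                digest = hash_file_content(
                    self._broker.stored_item_path(relpath), algorithm
                ).digest
                if digest != record["hash"]:
                    report.altered_hash.append((identifier, relpath))
        known = set(self.manifest["items"])
        report.unknown = sorted(self._broker.stored_identifiers() - known)
        return report

    # -- lifecycle guards ------------------------------------------------------

    def add_item(self, *args, **kwargs):
        raise StateError("Dataset {} is frozen; items can no longer be added".format(self.uri))

    def freeze(self):
        raise StateError("Dataset {} is already frozen".format(self.uri))


# ---------------------------------------------------------------------------
# module-level operations


def create_proto_dataset(
    name: str,
    base_uri: str,
    creator_username: str | None = None,
    config: Config | None = None,
) -> ProtoDataset:
    """Create a new, empty proto dataset under *base_uri*.

    A fresh UUID is assigned; the creator defaults to the configured
    username (ultimately the operating-system account name).
    """
    validate_name(name)
    config = config or load_config()
    base = parse_uri(base_uri)
    cls = broker_class_for_scheme(base.scheme)
    dataset_uuid = str(uuid_module.uuid4())
    uri = cls.dataset_uri(base, name, dataset_uuid)
    broker = cls(uri, config)
    if broker.exists():
        raise CollisionError("Something already exists at {}".format(uri.normalized_text))
    broker.create_structure()
    admin = {
        "uuid": dataset_uuid,
        "name": name,
        "state": "proto",
        "creator_username": creator_username or config.username,
        "format_version": FORMAT_VERSION,
    }
    broker.put_artifact("admin", _json_text(admin))
    return ProtoDataset(broker, admin)


def _load_admin(uri: str, config: Config | None):
    broker = broker_for(uri, config)
    if not broker.has_artifact("admin"):
        raise NotFoundError("No dataset found at {}".format(broker.uri.normalized_text))
    admin = json.loads(broker.get_artifact("admin"))
    return broker, admin


def load_dataset(uri: str, config: Config | None = None) -> Dataset:
    """Load a frozen dataset from *uri*; behavior is identical whatever
    broker serves the URI."""
    broker, admin = _load_admin(uri, config)
    if admin.get("state") != "frozen" or not broker.has_artifact("manifest"):
        raise ProtoDatasetError(
            "{} is a proto dataset; freeze it first or use the proto "
            "operations".format(broker.uri.normalized_text)
        )
    return Dataset(broker, admin)


def load_proto_dataset(uri: str, config: Config | None = None) -> ProtoDataset:
    """Load a dataset still under construction."""
    broker, admin = _load_admin(uri, config)
    if admin.get("state") != "proto":
        raise StateError(
            "{} is frozen; it can no longer be modified".format(broker.uri.normalized_text)
        )
    return ProtoDataset(broker, admin)


def copy_dataset(src_uri: str, dest_base_uri: str, config: Config | None = None) -> str:
    """Copy a frozen dataset to another base URI, possibly on a different
    storage medium, and return the destination dataset URI.

    The copy preserves UUID, name, readme text, overlays and the manifest
    byte-for-byte.  The administrative record is written last, so an
    interrupted copy never looks like a complete dataset.
    """
    config = config or load_config()
    src = load_dataset(src_uri, config)
    base = parse_uri(dest_base_uri)
    cls = broker_class_for_scheme(base.scheme)
    dest_uri = cls.dataset_uri(base, src.name, src.uuid)
    dest = cls(dest_uri, config)
    if dest.exists():
        raise CollisionError(
            "Dataset with UUID {} already exists at {}".format(
                src.uuid, dest_uri.normalized_text
            )
        )
    dest.create_structure()
    for identifier in src.identifiers:
        relpath = src.item_relpath(identifier)
        dest.put_item(src.broker.stored_item_path(relpath), relpath)
    dest.put_artifact("readme", src.get_readme())
    for overlay_name in src.list_overlay_names():
        dest.put_overlay_text(overlay_name, src.broker.get_overlay_text(overlay_name))
    dest.put_artifact("manifest", src.broker.get_artifact("manifest"))
    dest.put_artifact("admin", src.broker.get_artifact("admin"))
    return dest_uri.normalized_text


def summarize(dataset: Dataset) -> SummaryRecord:
    """Headline facts about a frozen dataset."""
    items = dataset.manifest["items"]
    return SummaryRecord(
        name=dataset.name,
        uuid=dataset.uuid,
        creator_username=dataset.creator_username,
        number_of_items=len(items),
        total_size_in_bytes=sum(rec["size_in_bytes"] for rec in items.values()),
        frozen_at=float(dataset.admin_record["frozen_at"]),
    )


def list_datasets(base_uri: str, config: Config | None = None) -> list[DatasetEntry]:
    """Datasets directly under *base_uri*, sorted by name then URI."""
    config = config or load_config()
    base = parse_uri(base_uri)
    cls = broker_class_for_scheme(base.scheme)
    entries = []
    for uri in cls.list_dataset_uris(base):
        broker = cls(uri, config)
        admin = json.loads(broker.get_artifact("admin"))
        entries.append(
            DatasetEntry(
                name=admin.get("name", ""),
                uri=uri.normalized_text,
                state=admin.get("state", "proto"),
            )
        )
    return sorted(entries, key=lambda e: (e.name, e.uri))


def list_identifiers(dataset: Dataset) -> list[str]:
    """Identifiers of a dataset's items, lexicographically sorted."""
    return dataset.identifiers


def iter_items(dataset: Dataset) -> Iterable[tuple[str, dict]]:
    """(identifier, item record) pairs in identifier order."""
    for identifier in dataset.identifiers:
        yield identifier, dataset.manifest["items"][identifier]
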