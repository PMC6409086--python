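"""Dataset lifecycle, manifests, verification and copying.

Every test here runs against both concrete storage brokers via the
``base_uri`` fixture: the dataset abstraction must behave identically on
a directory tree and on a flat, identifier-keyed object store.
"""

import json
import os
import random

import pytest

from datatote import (
    CollisionError,
    NotFoundError,
    ProtoDatasetError,
    StateError,
    ValidationError,
    copy_dataset,
    create_proto_dataset,
    list_datasets,
    load_dataset,
    load_proto_dataset,
    summarize,
)
from datatote.hashing import generate_identifier


def _build(base_uri, make_file, items, name="ds", readme=""):
    proto = create_proto_dataset(name, base_uri)
    for relpath, content in items:
        proto.add_item(make_file(content), relpath)
    if readme:
        proto.put_readme(readme)
    proto.freeze()
    return proto.uri


class TestCreate:
    def test_assigns_distinct_uuids(self, tmp_path):
        uuids = set()
        for i in range(2):
            base = tmp_path / "b{}".format(i)
            base.mkdir()
            uuids.add(create_proto_dataset("same-name", str(base)).uuid)
        assert len(uuids) == 2

    @pytest.mark.parametrize("bad", ["bad name!", "", "with space", "tab\tname"])
    def test_rejects_unsafe_names(self, base_uri, bad):
        with pytest.raises(ValidationError):
            create_proto_dataset(bad, base_uri)

    def test_admin_record_fields(self, base_uri):
        proto = create_proto_dataset("ds-name", base_uri, creator_username="olssont")
        admin = proto.admin_record
        assert admin["name"] == "ds-name"
        assert admin["state"] == "proto"
        assert admin["creator_username"] == "olssont"
        assert "frozen_at" not in admin
        # RFC-4122 textual form, lowercase
        assert len(admin["uuid"]) == 36
        assert admin["uuid"] == admin["uuid"].lower()

    def test_creator_defaults_to_configured_username(self, base_uri):
        assert create_proto_dataset("ds", base_uri).creator_username == "testuser"


class TestAddItem:
    def test_returns_identifier_of_relpath(self, base_uri, make_file):
        proto = create_proto_dataset("ds", base_uri)
        identifier = proto.add_item(make_file(b"hello"), "hello.txt")
        assert identifier == generate_identifier("hello.txt")

    def test_relpath_defaults_to_filename(self, base_uri, make_file):
        proto = create_proto_dataset("ds", base_uri)
        identifier = proto.add_item(make_file(b"x", name="hello.txt"))
        assert identifier == generate_identifier("hello.txt")

    def test_duplicate_relpath_replaces_content(self, base_uri, make_file):
        proto = create_proto_dataset("ds", base_uri)
        proto.add_item(make_file(b"old"), "a.txt")
        proto.add_item(make_file(b"new content"), "a.txt")
        ds = proto.freeze()
        assert len(ds.manifest["items"]) == 1
        record = ds.manifest["items"][generate_identifier("a.txt")]
        assert record["size_in_bytes"] == len(b"new content")

    def test_add_to_frozen_raises_state_error(self, base_uri, make_file):
        proto = create_proto_dataset("ds", base_uri)
        ds = proto.freeze()
        with pytest.raises(StateError):
            ds.add_item(make_file(b"x"), "a.txt")

    @pytest.mark.parametrize("bad", ["/abs/path.txt", "a/../b.txt", "./a.txt", ""])
    def test_rejects_unsafe_relpaths(self, base_uri, make_file, bad):
        proto = create_proto_dataset("ds", base_uri)
        with pytest.raises(ValidationError):
            proto.add_item(make_file(b"x"), bad)

    def test_unreadable_source_raises_oserror(self, base_uri, tmp_path):
        proto = create_proto_dataset("ds", base_uri)
        with pytest.raises(OSError):
            proto.add_item(str(tmp_path / "missing.bin"), "a.txt")


class TestFreeze:
    def test_manifest_keyed_by_identifiers(self, base_uri, make_file):
        uri = _build(base_uri, make_file, [("a.txt", b"aa"), ("sub/b.txt", b"bbb")])
        ds = load_dataset(uri)
        assert set(ds.manifest["items"]) == {
            generate_identifier("a.txt"),
            generate_identifier("sub/b.txt"),
        }
        for identifier, record in ds.manifest["items"].items():
            assert identifier == generate_identifier(record["relpath"])

    def test_records_size_hash_and_timestamp(self, base_uri, make_file):
        proto = create_proto_dataset("ds", base_uri)
        proto.add_item(make_file(b"hello", mtime=1537805410.0), "h.txt")
        ds = proto.freeze()
        record = ds.manifest["items"][generate_identifier("h.txt")]
        assert record["size_in_bytes"] == 5
        assert record["utc_timestamp"] == 1537805410.0
        import hashlib

        assert record["hash"] == hashlib.md5(b"hello").hexdigest()

    def test_empty_dataset_is_legal(self, base_uri):
        ds = create_proto_dataset("empty", base_uri).freeze()
        summary = summarize(ds)
        assert summary.number_of_items == 0
        assert summary.total_size_in_bytes == 0
        assert summary.size_text == "0.0B"
        assert ds.verify(full=True).ok

    def test_freeze_twice_raises(self, base_uri):
        proto = create_proto_dataset("ds", base_uri)
        ds = proto.freeze()
        with pytest.raises(StateError):
            ds.freeze()

    def test_frozen_at_set_to_now(self, base_uri):
        import time

        before = time.time()
        ds = create_proto_dataset("ds", base_uri).freeze()
        after = time.time()
        assert before <= ds.admin_record["frozen_at"] <= after

    def test_total_size_is_additive(self, base_uri, make_file):
        uri = _build(base_uri, make_file, [("a", b"x" * 7), ("b", b"y" * 13)])
        assert summarize(load_dataset(uri)).total_size_in_bytes == 20

    def test_manifest_serialized_sorted_two_space_indent(self, base_uri, make_file):
        uri = _build(base_uri, make_file, [("b.txt", b"b"), ("a.txt", b"a")])
        ds = load_dataset(uri)
        raw = ds.broker.get_artifact("manifest")
        assert raw == json.dumps(json.loads(raw), indent=2, sort_keys=True) + "\n"
        assert set(json.loads(raw)) == {"dtoolcore_version", "hash_function", "items"}
        assert json.loads(raw)["hash_function"] == "md5sum_hexdigest"


class TestLoad:
    def test_load_proto_uri_raises_distinct_error(self, base_uri):
        proto = create_proto_dataset("ds", base_uri)
        with pytest.raises(ProtoDatasetError):
            load_dataset(proto.uri)
        assert load_proto_dataset(proto.uri).uuid == proto.uuid

    def test_load_nothing_raises_not_found(self, base_uri):
        with pytest.raises(NotFoundError):
            load_dataset(base_uri.rstrip("/") + "/no-dataset-here")

    def test_load_proto_of_frozen_raises_state_error(self, base_uri):
        proto = create_proto_dataset("ds", base_uri)
        proto.freeze()
        with pytest.raises(StateError):
            load_proto_dataset(proto.uri)


class TestIdentifiersAndFetch:
    def test_identifiers_sorted_lexicographically(self, base_uri, make_file):
        items = [("ERR022075_1.fastq.gz", b"r1"), ("ERR022075_2.fastq.gz", b"r2")]
        ds = load_dataset(_build(base_uri, make_file, items))
        assert ds.identifiers == [
            "8bda245a8cd526673aab775f90206c8b67d196af",
            "9760280dc6313d3bb598fa03c5931a7f037d7ffc",
        ]
        assert ds.identifiers == sorted(ds.manifest["items"])

    def test_fetch_returns_readable_path_with_matching_content(self, base_uri, make_file):
        ds = load_dataset(_build(base_uri, make_file, [("payload.bin", b"\x00\x01payload")]))
        path = ds.fetch_item(generate_identifier("payload.bin"))
        assert os.path.isabs(path)
        with open(path, "rb") as fh:
            assert fh.read() == b"\x00\x01payload"

    def test_fetch_is_idempotent(self, base_uri, make_file):
        ds = load_dataset(_build(base_uri, make_file, [("a.txt", b"a")]))
        identifier = generate_identifier("a.txt")
        assert ds.fetch_item(identifier) == ds.fetch_item(identifier)

    def test_fetch_unknown_identifier_names_dataset_uri(self, base_uri, make_file):
        ds = load_dataset(_build(base_uri, make_file, [("a.txt", b"a")]))
        with pytest.raises(NotFoundError) as excinfo:
            ds.fetch_item("0" * 40)
        assert ds.uri in str(excinfo.value)


class TestVerify:
    def _corrupt(self, ds, relpath, new_bytes):
        path = ds.broker.stored_item_path(relpath)
        with open(path, "wb") as fh:
            fh.write(new_bytes)

    def test_intact_dataset_is_ok(self, base_uri, make_file):
        ds = load_dataset(_build(base_uri, make_file, [("a.txt", b"aaa"), ("b.txt", b"bb")]))
        report = ds.verify(full=True)
        assert report.ok

    def test_missing_item_reported(self, base_uri, make_file):
        ds = load_dataset(_build(base_uri, make_file, [("U00096.3.fasta", b">seq\nACGT\n")]))
        os.remove(ds.broker.stored_item_path("U00096.3.fasta"))
        report = ds.verify()
        assert not report.ok
        assert report.missing == [
            ("b445ff5a1e468ab48628a00a944cac2e007fb9bc", "U00096.3.fasta")
        ]

    def test_size_change_detected_by_default_mode(self, base_uri, make_file):
        ds = load_dataset(_build(base_uri, make_file, [("a.txt", b"aaa")]))
        self._corrupt(ds, "a.txt", b"aaaa")
        report = ds.verify()
        assert not report.ok
        assert report.altered_size == [(generate_identifier("a.txt"), "a.txt")]

    def test_byte_flip_needs_full_mode(self, base_uri, make_file):
        ds = load_dataset(_build(base_uri, make_file, [("a.txt", b"abc")]))
        self._corrupt(ds, "a.txt", b"abd")  # same size, different content
        assert ds.verify().ok
        full = ds.verify(full=True)
        assert not full.ok
        assert full.altered_hash == [(generate_identifier("a.txt"), "a.txt")]

    def test_extra_item_on_storage_reported_unknown(self, base_uri, make_file):
        ds = load_dataset(_build(base_uri, make_file, [("a.txt", b"a")]))
        ds.broker.put_item(make_file(b"stray"), "stray.txt")
        report = ds.verify()
        assert report.unknown == [generate_identifier("stray.txt")]

    def test_any_single_byte_corruption_detected_in_full_mode(self, base_uri, make_file):
        rng = random.Random(20260928)
        items = [
            ("reads/r{}.dat".format(i), bytes(rng.randrange(256) for _ in range(200)))
            for i in range(4)
        ]
        ds = load_dataset(_build(base_uri, make_file, items))
        for relpath, content in items:  # exhaustive over items
            for pos in rng.sample(range(len(content)), 5):  # sampled positions
                mutated = bytearray(content)
                mutated[pos] ^= 0x01
                self._corrupt(ds, relpath, bytes(mutated))
                report = ds.verify(full=True)
                assert report.altered_hash == [(generate_identifier(relpath), relpath)]
                self._corrupt(ds, relpath, content)
        assert ds.verify(full=True).ok


class TestLifecycleRoundTrip:
    def test_random_fixtures_round_trip(self, base_uri, make_file):
        rng = random.Random(42)
        for trial in range(3):
            n = rng.randint(0, 20)
            items = {}
            while len(items) < n:
                relpath = "d{}/f{}.bin".format(rng.randint(0, 3), rng.randint(0, 999))
                items[relpath] = bytes(rng.randrange(256) for _ in range(rng.randint(0, 500)))
            uri = _build(
                base_uri, make_file, sorted(items.items()), name="round-trip-{}".format(trial)
            )
            ds = load_dataset(uri)
            assert ds.identifiers == sorted(generate_identifier(rp) for rp in items)
            assert ds.verify(full=True).ok
            assert summarize(ds).total_size_in_bytes == sum(map(len, items.values()))


class TestCopy:
    def _fixture(self, base, make_file):
        proto = create_proto_dataset("copy-me", base, creator_username="olssont")
        proto.add_item(make_file(b"payload-1"), "one.txt")
        proto.add_item(make_file(b"payload-22"), "sub/two.txt")
        proto.put_readme("---\ndescription: original  # comment survives\n")
        ds = proto.freeze()
        ds.put_overlay(
            "is_first", {generate_identifier("one.txt"): True, generate_identifier("sub/two.txt"): False}
        )
        return ds

    def test_copy_preserves_identity_and_passes_full_verify(
        self, disk_base, mock_base, make_file
    ):
        src = self._fixture(disk_base, make_file)
        dest_uri = copy_dataset(src.uri, mock_base)
        dest = load_dataset(dest_uri)
        assert dest.uuid == src.uuid
        assert dest.name == src.name
        assert dest.get_readme() == src.get_readme()
        assert dest.get_overlay("is_first") == src.get_overlay("is_first")
        assert dest.broker.get_artifact("manifest") == src.broker.get_artifact("manifest")
        assert dest.verify(full=True).ok
        assert src.verify(full=True).ok

    def test_chain_disk_mock_disk_is_bit_identical(self, tmp_path, make_file):
        base_a = tmp_path / "a"
        base_a.mkdir()
        src = self._fixture(str(base_a), make_file)
        mock_uri = copy_dataset(src.uri, "mock://{}".format(tmp_path / "store"))
        base_b = tmp_path / "b"
        base_b.mkdir()
        final_uri = copy_dataset(mock_uri, str(base_b))
        final = load_dataset(final_uri)
        assert final.uuid == src.uuid
        assert final.broker.get_artifact("manifest") == src.broker.get_artifact("manifest")
        assert final.get_readme() == src.get_readme()
        for identifier in src.identifiers:
            with open(src.fetch_item(identifier), "rb") as fh_a, open(
                final.fetch_item(identifier), "rb"
            ) as fh_b:
                assert fh_a.read() == fh_b.read()
        assert final.verify(full=True).ok

    def test_returned_uri_loadable_with_unchanged_name(self, disk_base, mock_base, make_file):
        src = self._fixture(disk_base, make_file)
        assert load_dataset(copy_dataset(src.uri, mock_base)).name == "copy-me"

    def test_second_copy_to_same_base_collides(self, disk_base, mock_base, make_file):
        src = self._fixture(disk_base, make_file)
        copy_dataset(src.uri, mock_base)
        with pytest.raises(CollisionError) as excinfo:
            copy_dataset(src.uri, mock_base)
        assert src.uuid in str(excinfo.value)

    def test_copy_of_proto_rejected(self, disk_base, mock_base):
        proto = create_proto_dataset("still-open", disk_base)
        with pytest.raises(ProtoDatasetError):
            copy_dataset(proto.uri, mock_base)


class TestListDatasets:
    def test_entries_sorted_and_loadable(self, base_uri, make_file):
        for name in ["zeta", "alpha", "mid"]:
            _build(base_uri, make_file, [("x", b"x")], name=name)
        entries = list_datasets(base_uri)
        assert [e.name for e in entries] == ["alpha", "mid", "zeta"]
        for entry in entries:
            assert load_dataset(entry.uri).name == entry.name
            assert entry.state == "frozen"

    def test_empty_base(self, base_uri):
        assert list_datasets(base_uri) == []

    def test_proto_dataset_flagged(self, base_uri):
        create_proto_dataset("open-one", base_uri)
        entries = list_datasets(base_uri)
        assert len(entries) == 1
        assert entries[0].state == "proto"
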