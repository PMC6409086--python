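"""Deterministic fixture datasets for tests, demos and benchmarks.

Two flavors of fixture exist:

* *content fixtures* hold real (small, synthetic) item bytes — gzipped
  FASTQ-like paired reads, a FASTA fragment — and support every dataset
  operation including fetch and full verification;
* *manifest-level fixtures* declare item sizes, hashes and timestamps in
  the manifest without materializing any bytes, so a multi-GiB dataset can
  be emulated instantly.  They are interchangeable with content fixtures
  for every operation that never reads item bytes (name, uuid, summary,
  ls, identifiers) and are flagged as not fetchable.

All synthetic content is generated from the fixture's seed; the same spec
and seed produce identical manifests apart from the UUID (unless the UUID
is pinned explicitly).
"""

from __future__ import annotations

import gzip
import hashlib
import os
import random
import tempfile
import uuid as uuid_module
from dataclasses import dataclass, field

from .brokers import broker_class_for_scheme
from .config import Config, load_config
from .dataset import FORMAT_VERSION, MANIFEST_VERSION, ProtoDataset, _json_text
from .errors import ValidationError
from .hashing import DEFAULT_HASH_NAME, generate_identifier
from .uri import parse_uri

__all__ = [
    "FixtureItem",
    "FixtureSpec",
    "make_fixture_dataset",
    "paired_reads_spec",
    "reads_manifest_spec",
    "ref_genome_spec",
    "synthetic_fastq_gz",
]

# Manifest facts of the wild paired-read sequencing dataset used throughout
# the worked examples: two gzipped FASTQ files of ~1.8 GiB, frozen on
# 2018-09-26 (UTC).  Used by the manifest-level fixture so summaries and
# listings reproduce the published values without multi-GiB files.
READS_NAME = "Escherichia-coli-reads-ERR022075"
READS_UUID = "faa44606-cb86-4877-b9ea-643a3777e021"
READS_CREATOR = "olssont"
READS_FROZEN_AT = 1537963200.0  # noon UTC, 2018-09-26
READS_ITEMS = (
    ("ERR022075_1.fastq.gz", 1875702420, "4766e60e72da987e4c54e47fee5653a4", 1537805358.0),
    ("ERR022075_2.fastq.gz", 1982742623, "78608288625e084d68b4b5e8c1725933", 1537805410.0),
)


@dataclass(frozen=True)
class FixtureItem:
    """One item of a fixture: either real content or a declared size."""

    relpath: str
    content: bytes | None = None
    size: int | None = None
    hash: str | None = None
    utc_timestamp: float | None = None


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    items: tuple[FixtureItem, ...] = ()
    readme: str = ""
    seed: int = 0
    uuid: str | None = None
    creator_username: str | None = None
    frozen_at: float | None = None


def _fake_digest(seed: int, relpath: str) -> str:
    return hashlib.md5("{}:{}".format(seed, relpath).encode("utf-8")).hexdigest()


def make_fixture_dataset(spec: FixtureSpec, base_uri: str, config: Config | None = None) -> str:
    """Materialize *spec* as a frozen dataset under *base_uri* and return
    its URI.

    Items with real ``content`` are stored and hashed normally.  Items
    declaring only a ``size`` produce a manifest-level fixture: the
    manifest records the stated size (and hash/timestamp, faked
    deterministically from the seed when not given) but no bytes exist on
    storage, so such fixtures are not fetchable and fail verification by
    construction.  Mixing the two flavors in one spec is rejected.
    """
    declared = [item for item in spec.items if item.content is None]
    if declared and len(declared) != len(spec.items):
        raise ValidationError("A fixture spec must not mix content and declared-size items")

    config = config or load_config()
    base = parse_uri(base_uri)
    cls = broker_class_for_scheme(base.scheme)
    ds_uuid = spec.uuid or str(uuid_module.uuid4())
    uri = cls.dataset_uri(base, spec.name, ds_uuid)
    broker = cls(uri, config)
    broker.create_structure()
    admin = {
        "uuid": ds_uuid,
        "name": spec.name,
        "state": "proto",
        "creator_username": spec.creator_username or config.username,
        "format_version": FORMAT_VERSION,
    }
    broker.put_artifact("admin", _json_text(admin))
    broker.put_artifact("readme", spec.readme)

    default_frozen_at = spec.frozen_at if spec.frozen_at is not None else 1537963200.0

    if not declared:
        proto = ProtoDataset(broker, admin)
        with tempfile.TemporaryDirectory() as tmp:
            for index, item in enumerate(spec.items):
                path = os.path.join(tmp, "item-{}".format(index))
                with open(path, "wb") as fh:
                    fh.write(item.content)
                stamp = (
                    item.utc_timestamp
                    if item.utc_timestamp is not None
                    else 1537800000.0 + index
                )
                os.utime(path, (stamp, stamp))
                proto.add_item(path, item.relpath)
        proto.freeze()
        admin["frozen_at"] = default_frozen_at
        broker.put_artifact("admin", _json_text(admin))
    else:
        items = {}
        for index, item in enumerate(spec.items):
            items[generate_identifier(item.relpath)] = {
                "hash": item.hash or _fake_digest(spec.seed, item.relpath),
                "relpath": item.relpath,
                "size_in_bytes": int(item.size),
                "utc_timestamp": (
                    item.utc_timestamp
                    if item.utc_timestamp is not None
                    else 1537800000.0 + index
                ),
            }
        manifest = {
            "dtoolcore_version": MANIFEST_VERSION,
            "hash_function": DEFAULT_HASH_NAME,
            "items": items,
        }
        broker.put_artifact("manifest", _json_text(manifest))
        admin["state"] = "frozen"
        admin["frozen_at"] = default_frozen_at
        broker.put_artifact("admin", _json_text(admin))
    return uri.normalized_text


# ---------------------------------------------------------------------------
# synthetic content generators


_DNA = "ACGT"


def synthetic_fastq_gz(
    seed: int, read_number: int, n_records: int = 25, read_length: int = 100
) -> bytes:
    """Gzipped FASTQ-like content emulating one side of a paired-read run.

    The first record header is pinned to the run/tile/coordinate form seen
    in real paired data so scripts that inspect the first line have a
    stable target; the remaining records are random.  Output is a
    deterministic function of (seed, read_number).
    """
    rng = random.Random("fastq:{}:{}".format(seed, read_number))
    lines = []
    for i in range(1, n_records + 1):
        if i == 1:
            x, y = 1158, 949
        else:
            x, y = rng.randint(1, 2000), rng.randint(1, 2000)
        lines.append("@ERR022075.{} EAS600_70:5:1:{}:{}/{}".format(i, x, y, read_number))
        lines.append("".join(rng.choice(_DNA) for _ in range(read_length)))
        lines.append("+")
        lines.append("".join(chr(33 + rng.randint(2, 40)) for _ in range(read_length)))
    data = ("\n".join(lines) + "\n").encode("ascii")
    return gzip.compress(data, mtime=0)


def synthetic_fasta(seed: int, header: str, length: int = 2000) -> bytes:
    """A synthetic FASTA record (random DNA); a stand-in for a reference
    sequence, not real genomic data."""
    rng = random.Random("fasta:{}:{}".format(seed, header))
    seq = "".join(rng.choice(_DNA) for _ in range(length))
    body = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
    return (">{}\n{}\n".format(header, body)).encode("ascii")


def paired_reads_spec(seed: int = 0, n_records: int = 25) -> FixtureSpec:
    """A small content fixture shaped like a paired-read sequencing
    dataset: two gzipped FASTQ items with matching read headers."""
    return FixtureSpec(
        name=READS_NAME + "-minified",
        items=(
            FixtureItem(
                relpath="ERR022075_1.fastq.gz",
                content=synthetic_fastq_gz(seed, 1, n_records),
                utc_timestamp=1537805358.0,
            ),
            FixtureItem(
                relpath="ERR022075_2.fastq.gz",
                content=synthetic_fastq_gz(seed, 2, n_records),
                utc_timestamp=1537805410.0,
            ),
        ),
        readme="---\ndescription: synthetic paired-end reads (minified)\n",
        seed=seed,
    )


def reads_manifest_spec() -> FixtureSpec:
    """Manifest-level fixture reproducing the published paired-read
    dataset's administrative and structural metadata exactly (sizes,
    hashes, timestamps, UUID, creator, freeze date) without any bytes."""
    return FixtureSpec(
        name=READS_NAME,
        items=tuple(
            FixtureItem(relpath=rp, size=size, hash=digest, utc_timestamp=stamp)
            for rp, size, digest, stamp in READS_ITEMS
        ),
        readme="---\ndescription: Whole Genome Sequencing of Escherichia coli str. K-12 MG1655\n",
        uuid=READS_UUID,
        creator_username=READS_CREATOR,
        frozen_at=READS_FROZEN_AT,
    )


def ref_genome_spec(seed: int = 0) -> FixtureSpec:
    """Content fixture shaped like a reference-genome dataset with a single
    FASTA item named ``U00096.3.fasta`` (synthetic sequence)."""
    return FixtureSpec(
        name="Escherichia-coli-ref-genome",
        items=(
            FixtureItem(
                relpath="U00096.3.fasta",
                content=synthetic_fasta(seed, "U00096.3 synthetic fragment"),
                utc_timestamp=1537805000.0,
            ),
        ),
        readme="---\ndescription: reference genome (synthetic stand-in)\n",
        seed=seed,
    )
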