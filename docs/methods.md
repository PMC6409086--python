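# Methods

## The dataset model

A dataset is a set of item files plus three metadata layers.
Administrative metadata (JSON) carries a UUID assigned at creation and
never changed — including across copies, so the UUID identifies the
dataset, not its location — along with name, creator username, lifecycle
state (`proto` or `frozen`), a format-version string and, once frozen, the
freeze time as UTC epoch seconds. Structural metadata is the manifest
(JSON): a map from item identifier to `{relpath, size_in_bytes, hash,
utc_timestamp}`. Descriptive metadata is the free-form YAML readme and
per-item overlays.

The lifecycle is deliberately one-way: items can only be added to a proto
dataset, and freezing recomputes everything — sizes, checksums,
timestamps — from the bytes actually on storage rather than from the
history of `add_item` calls. Storage is the single source of truth, so a
freeze after out-of-band manipulation still yields a manifest that
describes reality. `utc_timestamp` is the stored file's modification time
at freeze, kept as a decimal number.

Assumptions: one writer at a time (no locking), items are ordinary files
(no directories-as-items, no symlink semantics), and relpaths are
forward-slash separated with no absolute or `.`/`..` segments.

## Identifiers and fixity

An item identifier is `SHA1(UTF8(relpath))` — 40 lowercase hex characters,
a pure function of the relative path. Using the *path* rather than the
content means an identifier is stable when content is regenerated, and
computable without reading any bytes; content integrity is the manifest's
job, not the identifier's. Identifier ordering everywhere (listings,
reports) is plain byte-wise lexicographic on the hex text.

Content fixity uses a checksum registry keyed by the manifest's
`hash_function` label. The default is MD5 under the label
`md5sum_hexdigest`; SHA-1 and SHA-256 are also registered, and the label
stored in a manifest is authoritative when verifying, so datasets written
with any registered algorithm verify correctly. Files are hashed in fixed
64 KiB chunks: memory use is independent of item size, which matters for
multi-GiB sequencing files. This is an integrity check against accident —
bit rot, truncated transfers, misplaced files — not against an adversary:
anyone who can edit the items can edit the manifest too, and MD5/SHA-1
offer no collision resistance. Tamper-proofing is explicitly out of scope.

`verify` has two modes because hashing is the expensive step: the default
mode checks identifier presence and size equality only (fast even for
huge datasets, and sufficient for truncation and loss), while `--full`
re-hashes every item. A flipped byte that preserves size is therefore
invisible to the default mode by design and caught by full mode; the
report also lists items present on storage but absent from the manifest
as *unknown*. Discrepancies are report content, never exceptions.

## Size formatting

Sizes are rendered with binary prefixes (1 KiB = 1024 B), choosing the
largest unit with value ≥ 1 (plain bytes below 1024), one decimal place,
rounded half-up on the decimal, no space before the unit. Half-up rather
than banker's rounding keeps the result a monotone function of the byte
count in the (unit, value) ordering; truncation is ruled out because a
3.593 GiB total must read 3.6 GiB. Values like `1024.0KiB` can appear in
the sliver between 1024 × 1024ᵖ − rounding margin and 1024ᵖ⁺¹; we accept
this rather than special-casing the carry.

## Storage brokers

All medium access is behind a broker contract (create structure; get/put
the four named text artefacts; get/put/enumerate items; report per-item
size and timestamp; expose a local readable path; enumerate datasets
under a base URI). Two brokers ship:

- **Disk** (`file://`): dataset at `<base>/<name>`, items under `data/` at
  their relpaths, bookkeeping under `.dtool/` (`dtool` = admin record,
  `manifest.json`, `structure.json`, `README.txt`, `overlays/`). These
  names are format constants of the established on-disk dataset layout, so
  the directories we write interoperate with other tools that read it.
  `structure.json` maps logical artefact names to locations, and
  `README.txt` is a fixed note telling a human the directory is a managed
  dataset.
- **Local object store** (`mock://<store>/<uuid>`): datasets addressed by
  UUID, metadata as flat key files, item bytes stored flat under
  `data/<identifier>` with a `handle.<identifier>` key recording the
  relpath (needed to enumerate items at freeze). `fetch_item` copies the
  blob into a per-UUID cache directory (configurable via config file or
  `DATATOTE_CACHE_DIRECTORY`; writes go through a `.part` rename so a
  half-written cache entry is never returned) and reuses it on later
  fetches. This broker exists to prove the path abstraction: nothing on
  the medium mirrors the relpath tree, yet every dataset operation behaves
  identically — the whole test suite is parametrized over both brokers.

A dataset is recognised by the presence of its admin record, and the
admin record is always written last during a copy, so an interrupted copy
is never mistaken for a complete dataset — a cheap atomicity signal that
needs no transactions. Copies transfer the manifest, readme and overlays
as raw text (byte-identical) rather than re-serializing; a copy to a base
that already holds the UUID is a collision error. Network brokers (S3,
Azure, iRODS, HTTP) and publishing ACLs are out of scope; their schemes
produce a "not supported in this build" error.

Proto state is signalled by `state` in the admin record together with the
absence of a manifest; URIs normalize bare paths to absolute `file://`
form, idempotently.

## Descriptive metadata

The readme is stored and compared as raw text: user formatting, comments
and key order survive round trips, and a YAML parse failure never blocks
storage or display (the raw text is authoritative, parsing is
best-effort). Readme writes are allowed on frozen datasets — descriptive
metadata is curatorial, not structural — while the manifest and admin
record stay immutable after freeze. The interactive template's key set
(`description`, `project`, `confidential`,
`personally_identifiable_information`, `owners`, `creation_date`) is a
repository convention; the readme is free-form YAML and projects may use
any schema.

Overlays are one JSON document per name, keys sorted; every key must be a
manifest identifier at write time and every value a scalar (text, number,
boolean, null). Nested values are rejected to keep overlays queryable.
Re-adding an item relpath before freeze replaces the previous content
(last write wins) — identifiers stay stable and the "paths are
abstracted" semantics hold. Empty (zero-item) frozen datasets are legal;
nothing in the format forbids them and they simplify pipeline edge cases.

## Command line conventions

`frozen_at` is rendered as a UTC ISO date (`YYYY-MM-DD`). Exit codes: 0
success, 1 user/validation error, 2 integrity failure from `verify` —
fixed for scriptability. Machine-consumed output (quiet forms,
identifiers, fetched paths) is one item per line on stdout; errors are a
single line on stderr (tracebacks only with `--debug`). Column separation
in listings is at-least-two-spaces, not fixed width. The `verify`
wordings `Unknown item: <id>` and `Altered item: <id> <relpath>` are
conventions of this package ("All good :)" and "Missing item: …" follow
the established transcript forms). `publish` is registered for
command-tree compatibility and reports that no network backend exists in
this build.

## Fixture generation

The fixture generator emulates the data this tool is typically pointed
at, at desk scale:

- *content fixtures* with real bytes: gzipped FASTQ-like paired reads
  (deterministic records from a seeded RNG, first header pinned to the
  run/tile/coordinate form of real paired-end Illumina data, gzip mtime
  zeroed for byte-reproducibility) and a synthetic FASTA stand-in for a
  reference sequence — random DNA, not real genomic data;
- *manifest-level fixtures* that declare item sizes, hashes and
  timestamps in the manifest without materializing bytes, so a 3.6 GiB
  two-item sequencing dataset is emulated instantly. They are
  interchangeable with content fixtures for every operation that never
  reads item bytes (name, uuid, summary, ls, identifiers) and fail
  verification by construction — which the tests rely on.

What passing tests do not show about real data: fixtures are tiny (items
of bytes to kilobytes; round-trip tests use up to 20 items), so
performance on multi-GiB items is asserted only structurally (chunked
hashing); the synthetic FASTQ/FASTA content exercises file handling, not
biology; and the object-store broker emulates remote semantics
(identifier-keyed blobs, fetch-through-cache) on a local disk, so network
failure modes — latency, partial uploads, eventual consistency — are
untested.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by choice:
random round-trip fixtures of ≤ 20 items of ≤ 500 bytes, corruption
sweeps exhaustive over items and sampled over byte positions (3–5 per
item), property tests at 50 derandomized examples. All randomness is
seeded (the acceptance script derives everything from `--seed`); fixture
timestamps are pinned so transcript outputs are stable. The suite
completes in well under a minute on one CPU.

## Known limitations

No concurrent multi-writer safety; no dataset deletion or retention
policy; no versioning of frozen datasets; no schema validation of user
YAML; no metadata search index; no tamper evidence (see above). Relpath
handling assumes POSIX separators; Windows paths are normalized only at
the CLI boundary by the underlying libraries.
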