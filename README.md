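# datatote

`datatote` packages data files together with their metadata into a single
portable, verifiable unit called a **dataset**, and gives you a command
line tool (`tote`) and Python API for creating, inspecting, copying and
verifying datasets wherever they are stored.

It is aimed at the people who actually shepherd research data day to day —
bioinformaticians embedded in research groups, core-facility staff,
students inheriting a predecessor's sequencing runs — in environments with
no central data-management system and a mixture of storage technologies.
Metadata encoded in file names and directory trees is lost the moment the
files move; `datatote` instead stores it *with* the data, so a dataset can
be archived, copied to cheaper storage, or handed to a collaborator
without losing its meaning or its integrity evidence.

## The model

A dataset bundles three kinds of metadata around its item files:

- **administrative** — a UUID (stable across copies), a name, the creator's
  username, the lifecycle state and the freeze timestamp;
- **structural** — the *manifest*: for every item its relative path, size
  in bytes, content checksum (MD5 by default, recorded under the label
  `md5sum_hexdigest`) and modification timestamp;
- **descriptive** — a free-form YAML README describing the science, plus
  named *overlays* mapping individual items to scalar annotations
  (e.g. `is_read1: true`).

Each item is addressed by an **identifier**: the SHA-1 hex digest of the
UTF-8 encoding of its relative path,

```
id(item) = SHA1(UTF8(relpath)),    e.g.  id("ERR022075_2.fastq.gz")
                                         = 8bda245a8cd526673aab775f90206c8b67d196af
```

so the same logical item keeps the same identifier on a filesystem, in an
object store, and across copies. A dataset begins life as a mutable
*proto dataset*; **freezing** computes the manifest from the stored bytes
and makes it immutable. From then on `verify` establishes *fixity*: the
default check confirms every expected identifier is present with the
recorded size, and `verify --full` recomputes the checksums.

All storage access goes through a pluggable **storage broker** contract.
This build ships two brokers — a directory-tree broker (`file://`, the
layout is the widely used `.dtool/` on-disk dataset format) and a local
object-store broker (`mock://`) that stores item bytes flat under
identifier keys and materializes them through a cache on fetch — and the
entire test suite runs identically against both.

## A worked example

```console
$ tote create -q my-first-ds .
file:///tmp/demo/my-first-ds
$ echo "hello world" > hello.txt
$ tote add item hello.txt my-first-ds
$ tote freeze my-first-ds
Dataset frozen file:///tmp/demo/my-first-ds: 1 items totalling 12.0B
$ tote summary my-first-ds
name: my-first-ds
uuid: 23b64184-aae3-4920-ae9d-775f569fde52
creator_username: olssont
number_of_items: 1
size: 12.0B
frozen_at: 2026-09-28
$ tote ls --verbose my-first-ds
3857b672471862eab426eba0622e44bd2cedbd5d  12.0B  hello.txt
$ tote verify my-first-ds
All good :)
```

The `summary` lines are the dataset's administrative facts plus the item
count and total size; the `ls --verbose` line shows each item's
identifier, formatted size and relative path; `verify` reports
`All good :)` only when storage matches the manifest exactly (a removed
item would print `Missing item: <identifier> <relpath>` and exit
non-zero).

Because commands compose on URIs, storage-agnostic pipelines are plain
shell (see `examples/simple_processing.sh` and `examples/minify.sh`):

```console
$ tote cp -q file:///tmp/demo/my_datasets/Escherichia-coli-ref-genome mock:///tmp/demo/store
mock:///tmp/demo/store/869c7cbc-38e8-4e59-b60f-3fc9882367b8
$ tote verify -f mock:///tmp/demo/store/869c7cbc-38e8-4e59-b60f-3fc9882367b8
All good :)
```

The copy keeps the UUID, name, readme, overlays and manifest; full
verification passes on the other medium. `tote ls BASE_URI` lists the
datasets under a base location and `tote inventory --format=html BASE_URI`
renders them as a shareable report (also `csv`/`json`).

The `datatote.fixtures` module generates deterministic fixture datasets —
small synthetic gzipped paired-read FASTQ items, a synthetic FASTA, and
*manifest-level* fixtures that declare multi-GiB item sizes without
writing the bytes — so every example above runs in milliseconds.

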