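"""Inventory reports: one row per frozen dataset under a base URI.

The same rows are rendered as CSV, JSON or a single self-contained HTML
page, so a directory (or object store) full of datasets can be summarised
and shared.  Generation is read-only.
"""

from __future__ import annotations

import csv
import datetime
import html
import io
import json
from dataclasses import asdict, dataclass

from .config import Config
from .dataset import list_datasets, load_dataset, summarize
from .errors import ValidationError

__all__ = ["InventoryRow", "build_inventory", "gather_rows"]

FIELDS = (
    "name",
    "uuid",
    "creator_username",
    "number_of_items",
    "size",
    "frozen_at",
    "uri",
)


@dataclass(frozen=True)
class InventoryRow:
    name: str
    uuid: str
    creator_username: str
    number_of_items: int
    size: str
    frozen_at: str
    uri: str


def _iso_date(epoch: float) -> str:
    return datetime.datetime.fromtimestamp(epoch, tz=datetime.timezone.utc).date().isoformat()


def gather_rows(base_uri: str, config: Config | None = None) -> list[InventoryRow]:
    """One row per frozen dataset under *base_uri*, sorted by name."""
    rows = []
    for entry in list_datasets(base_uri, config):
        if entry.state != "frozen":
            continue
        summary = summarize(load_dataset(entry.uri, config))
        rows.append(
            InventoryRow(
                name=summary.name,
                uuid=summary.uuid,
                creator_username=summary.creator_username,
                number_of_items=summary.number_of_items,
                size=summary.size_text,
                frozen_at=_iso_date(summary.frozen_at),
                uri=entry.uri,
            )
        )
    return rows


def _render_csv(rows: list[InventoryRow]) -> str:
    buffer = io.StringIO()
    writer = csv.DictWriter(buffer, fieldnames=FIELDS, lineterminator="\n")
    writer.writeheader()
    for row in rows:
        writer.writerow(asdict(row))
    return buffer.getvalue()


def _render_json(rows: list[InventoryRow]) -> str:
    return json.dumps([asdict(row) for row in rows], indent=2) + "\n"


def _render_html(rows: list[InventoryRow]) -> str:
    # Deliberately minimal static markup: no scripts, no external assets,
    # so the report is a single file that renders anywhere.
    head = "".join("<th>{}</th>".format(html.escape(f)) for f in FIELDS)
    body_rows = []
    for row in rows:
        cells = "".join(
            "<td>{}</td>".format(html.escape(str(value)))
            for value in (
                row.name,
                row.uuid,
                row.creator_username,
                row.number_of_items,
                row.size,
                row.frozen_at,
                row.uri,
            )
        )
        body_rows.append("    <tr>{}</tr>".format(cells))
    return (
        "<!DOCTYPE html>\n"
        "<html>\n<head>\n<meta charset=\"utf-8\">\n"
        "<title>Dataset inventory</title>\n"
        "<style>table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:0.3em 0.6em;text-align:left}</style>\n"
        "</head>\n<body>\n<h1>Dataset inventory</h1>\n<table>\n"
        "    <tr>" + head + "</tr>\n" + "\n".join(body_rows) + ("\n" if body_rows else "")
        + "</table>\n</body>\n</html>\n"
    )


_RENDERERS = {"csv": _render_csv, "json": _render_json, "html": _render_html}


def build_inventory(base_uri: str, format: str = "html", config: Config | None = None) -> str:
    """Render the inventory of *base_uri* in the requested format."""
    try:
        renderer = _RENDERERS[format]
    except KeyError:
        raise ValidationError(
            "Unknown inventory format {!r}; choose from {}".format(
                format, ", ".join(sorted(_RENDERERS))
            )
        ) from None
    return renderer(gather_rows(base_uri, config))
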