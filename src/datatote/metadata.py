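"""Descriptive metadata: the dataset readme and per-item overlays.

The readme is user-supplied YAML describing the dataset's scientific
context.  It is stored and compared as raw text — user formatting and
comments survive round-trips — and a parse failure never blocks storage or
display, because the raw text is authoritative.

Overlays attach one scalar value per item, keyed by item identifier:
for example ``is_read1`` mapping each item of a paired-read dataset to
``true`` or ``false``.  Values are restricted to scalars so overlays stay
queryable.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass

import yaml

from .errors import ValidationError

__all__ = ["DescriptiveMetadata", "parse_readme", "readme_template", "validate_overlay"]

_SAFE_NAME_RE = re.compile(r"^[A-Za-z0-9._-]+$")

#: Keys of the default readme template, in the order they are written.
#: This key set is a repository convention; projects can extend it freely
#: since the readme is free-form YAML.
TEMPLATE_KEYS = (
    "description",
    "project",
    "confidential",
    "personally_identifiable_information",
    "owners",
    "creation_date",
)


@dataclass(frozen=True)
class DescriptiveMetadata:
    """Raw readme text plus a best-effort parse of it."""

    raw_text: str
    parsed: object  # mapping on success, None when the YAML does not parse


def parse_readme(text: str) -> DescriptiveMetadata:
    try:
        parsed = yaml.safe_load(text)
    except yaml.YAMLError:
        parsed = None
    return DescriptiveMetadata(raw_text=text, parsed=parsed)


def readme_template(interactive_answers: dict | None = None) -> str:
    """Render the default descriptive-metadata template as YAML text.

    The template prompts for a description, the project name, whether the
    dataset contains confidential or personally identifiable information,
    the owners, and a creation date.  *interactive_answers* override the
    defaults key by key.
    """
    data = {
        "description": "",
        "project": "",
        "confidential": False,
        "personally_identifiable_information": False,
        "owners": [{"name": "", "email": ""}],
        "creation_date": datetime.date.today().isoformat(),
    }
    if interactive_answers:
        data.update(interactive_answers)
    body = yaml.safe_dump(data, sort_keys=False, default_flow_style=False, allow_unicode=True)
    return "---\n" + body


def validate_overlay(name: str, mapping: dict, manifest_identifiers: set[str]) -> None:
    """Check an overlay before it is written.

    Every key must be an identifier in the dataset's manifest and every
    value a scalar (text, number, boolean or null); nested structures are
    rejected.
    """
    if not _SAFE_NAME_RE.match(name or ""):
        raise ValidationError(
            "Invalid overlay name {!r}: use only letters, digits, '.', '-' "
            "and '_'".format(name)
        )
    for key, value in mapping.items():
        if key not in manifest_identifiers:
            raise ValidationError(
                "Overlay key {!r} is not an item identifier in the manifest".format(key)
            )
        if not (value is None or isinstance(value, (str, int, float, bool))):
            raise ValidationError(
                "Overlay value for {!r} must be a scalar, got {}".format(
                    key, type(value).__name__
                )
            )
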