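"""User-level configuration: creator username and item cache directory.

Values are resolved in order: environment variable, configuration file,
built-in default.  The configuration file is JSON at
``~/.config/datatote/config.json`` (override the path with
``DATATOTE_CONFIG``) with optional keys ``username`` and
``cache_directory``.
"""

from __future__ import annotations

import getpass
import json
import os
from dataclasses import dataclass

ENV_CONFIG = "DATATOTE_CONFIG"
ENV_USERNAME = "DATATOTE_USERNAME"
ENV_CACHE = "DATATOTE_CACHE_DIRECTORY"


def default_config_path() -> str:
    return os.path.join(os.path.expanduser("~"), ".config", "datatote", "config.json")


def default_cache_directory() -> str:
    return os.path.join(os.path.expanduser("~"), ".cache", "datatote")


@dataclass(frozen=True)
class Config:
    username: str
    cache_directory: str


def _read_config_file() -> dict:
    path = os.environ.get(ENV_CONFIG, default_config_path())
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except (OSError, ValueError):
        return {}
    return data if isinstance(data, dict) else {}


def load_config() -> Config:
    """Resolve the effective configuration for this process."""
    file_cfg = _read_config_file()
    username = os.environ.get(ENV_USERNAME) or file_cfg.get("username") or getpass.getuser()
    cache = (
        os.environ.get(ENV_CACHE)
        or file_cfg.get("cache_directory")
        or default_cache_directory()
    )
    return Config(username=str(username), cache_directory=str(cache))
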