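"""Flat key-value configuration dialect used package-wide.

One line per entry, ``section.key = value``; ``#`` starts a comment; order
is preserved so a file round-trips.  Values are stored as strings; typed
accessors convert on demand.  The same dialect serves model-parameter
configs, sweep-bundle manifests and ground-truth sidecars, keeping every
on-disk artifact diff-able plain text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["ConfigError", "parse_config", "format_config", "load_config",
           "save_config", "KeyValueConfig"]


class ConfigError(ValueError):
    """Malformed key-value config input."""


class KeyValueConfig(dict):
    """Ordered string→string mapping with typed accessors and prefix views."""

    def get_float(self, key: str, default: float | None = None) -> float:
        if key not in self:
            if default is None:
                raise ConfigError(f"missing required key: {key}")
            return default
        try:
            return float(self[key])
        except ValueError as exc:
            raise ConfigError(f"key {key!r} is not numeric: {self[key]!r}") from exc

    def get_int(self, key: str, default: int | None = None) -> int:
        if key not in self:
            if default is None:
                raise ConfigError(f"missing required key: {key}")
            return default
        try:
            return int(self[key])
        except ValueError as exc:
            raise ConfigError(f"key {key!r} is not an integer: {self[key]!r}") from exc

    def get_str(self, key: str, default: str | None = None) -> str:
        if key not in self:
            if default is None:
                raise ConfigError(f"missing required key: {key}")
            return default
        return self[key]

    def section(self, prefix: str) -> "KeyValueConfig":
        """All entries under ``prefix.``, with the prefix stripped."""
        dotted = prefix.rstrip(".") + "."
        return KeyValueConfig(
            (k[len(dotted):], v) for k, v in self.items() if k.startswith(dotted)
        )


def parse_config(text: str) -> KeyValueConfig:
    config = KeyValueConfig()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if not key:
            raise ConfigError(f"line {lineno}: empty key in {raw!r}")
        config[key] = value.strip()
    return config


def format_config(entries: Mapping[str, object] | Iterable[tuple[str, object]]) -> str:
    items = entries.items() if isinstance(entries, Mapping) else entries
    return "".join(f"{key} = {value}\n" for key, value in items)


def load_config(path: str | Path) -> KeyValueConfig:
    return parse_config(Path(path).read_text())


def save_config(entries: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(format_config(entries))
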