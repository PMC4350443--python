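"""Function and namespace registries for the restricted BEL dialect.

The registries are data, not code: the default tables ship with the package
as two-column TSV files (prefix, long name) and can be replaced or extended
with user-supplied TSVs of the same shape.  Prefixes are case-sensitive and
must be unique within a registry.
"""
from __future__ import annotations

import io
from collections.abc import Mapping
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterator, Union


class RegistryError(ValueError):
    """Raised for malformed or conflicting registry definitions."""


class Registry(Mapping):
    """Immutable mapping from a short prefix to its long description."""

    kind: str = "registry"

    def __init__(self, entries: Mapping[str, str] | Iterator[tuple[str, str]]):
        pairs = list(entries.items()) if isinstance(entries, Mapping) else list(entries)
        self._entries: dict[str, str] = {}
        for prefix, description in pairs:
            if not prefix:
                raise RegistryError(f"empty {self.kind} prefix")
            if prefix in self._entries:
                raise RegistryError(f"duplicate {self.kind} prefix: {prefix!r}")
            self._entries[prefix] = description

    def __getitem__(self, key: str) -> str:
        return self._entries[key]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        return f"{type(self).__name__}({len(self)} entries)"

    def extended(self, extra: Mapping[str, str]) -> "Registry":
        """Return a new registry with ``extra`` rows appended."""
        merged = list(self._entries.items()) + list(extra.items())
        return type(self)(merged)

    @classmethod
    def from_tsv(cls, source: Union[str, Path]) -> "Registry":
        """Load a registry from a two-column TSV file path or literal text."""
        if isinstance(source, Path) or (isinstance(source, str) and "\t" not in source):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source
        rows = []
        for lineno, line in enumerate(io.StringIO(text), start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RegistryError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
        return cls(rows)

    @classmethod
    def default(cls) -> "Registry":
        raise NotImplementedError


class FunctionRegistry(Registry):
    """The 28 BEL function prefixes (abundances, activities, processes...)."""

    kind = "function"
    _default_file = "bel_functions.tsv"

    @classmethod
    def default(cls) -> "FunctionRegistry":
        return _default_functions()


class NamespaceRegistry(Registry):
    """The namespace prefixes naming the vocabularies entities come from."""

    kind = "namespace"
    _default_file = "bel_namespaces.tsv"

    @classmethod
    def default(cls) -> "NamespaceRegistry":
        return _default_namespaces()


def _load_packaged(cls):
    text = resources.files("belnet.data").joinpath(cls._default_file).read_text("utf-8")
    return cls.from_tsv(text)


@lru_cache(maxsize=1)
def _default_functions() -> FunctionRegistry:
    return _load_packaged(FunctionRegistry)


@lru_cache(maxsize=1)
def _default_namespaces() -> NamespaceRegistry:
    return _load_packaged(NamespaceRegistry)
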