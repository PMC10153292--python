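"""Parameter catalog and parameter sets.

The shipped ``data/catalog.yaml`` names the model's 53 kinetic parameters
(for the default 4-cell build), tags their roles, and flags the 48 that the
robustness screens sample on log scales.  Five translation rate constants
are unsampled and default to ln2 / (product protein half-life), which is
the normalization that keeps every species' attainable range at [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import yaml

__all__ = ["CatalogEntry", "ParameterCatalog", "ParameterSet", "load_catalog"]


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    role: str
    default: float | None
    sampled: bool
    lo: float | None = None
    hi: float | None = None
    tied: str | None = None

    def __post_init__(self) -> None:
        if self.sampled:
            if self.lo is None or self.hi is None:
                raise ValueError(f"sampled parameter {self.name} needs a range")
            if not (0 < self.lo <= self.hi):
                raise ValueError(
                    f"range for {self.name} must satisfy 0 < lo <= hi, "
                    f"got ({self.lo}, {self.hi})"
                )
        if self.default is None and self.tied is None:
            raise ValueError(f"parameter {self.name} has neither default nor tie")


class ParameterCatalog:
    """Ordered collection of :class:`CatalogEntry`."""

    def __init__(self, entries: list[CatalogEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in catalog")
        self.entries: tuple[CatalogEntry, ...] = tuple(entries)
        self._by_name = {e.name: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> CatalogEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown parameter: {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def sampled_names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.sampled)

    def defaults(self) -> "ParameterSet":
        """Parameter set at catalog defaults (ties resolved)."""
        return ParameterSet({e.name: e.default for e in self.entries}, catalog=self)


_CATALOG_CACHE: ParameterCatalog | None = None


def load_catalog(path: str | None = None) -> ParameterCatalog:
    """Load the shipped catalog (cached), or a user-supplied YAML file."""
    global _CATALOG_CACHE
    if path is None and _CATALOG_CACHE is not None:
        return _CATALOG_CACHE
    if path is None:
        text = (resources.files("segpol") / "data" / "catalog.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    entries = []
    for item in raw["parameters"]:
        rng = item.get("range")
        entries.append(
            CatalogEntry(
                name=item["name"],
                role=item["role"],
                default=item.get("default"),
                sampled=bool(item.get("sampled", False)),
                lo=None if rng is None else float(rng[0]),
                hi=None if rng is None else float(rng[1]),
                tied=item.get("tied"),
            )
        )
    cat = ParameterCatalog(entries)
    if path is None:
        _CATALOG_CACHE = cat
    return cat


class ParameterSet(Mapping[str, float]):
    """Named parameter values, complete against a catalog.

    Entries whose value is None fall back to their tie
    (ln2 / value of the referenced half-life) on resolution.
    """

    def __init__(self, values: Mapping[str, float | None], catalog: ParameterCatalog | None = None):
        self.catalog = catalog or load_catalog()
        missing = set(self.catalog.names) - set(values)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        unknown = set(values) - set(self.catalog.names)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        self._raw = dict(values)
        self._resolved = self._resolve()

    def _resolve(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.catalog.entries:
            v = self._raw[e.name]
            if v is None:
                ref = self._raw[e.tied]
                if ref is None:
                    raise ValueError(f"tie target {e.tied} of {e.name} is unresolved")
                v = math.log(2.0) / float(ref)
            out[e.name] = float(v)
        return out

    def __getitem__(self, name: str) -> float:
        return self._resolved[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._resolved)

    def __len__(self) -> int:
        return len(self._resolved)

    def replace(self, **updates: float) -> "ParameterSet":
        vals = dict(self._raw)
        for k, v in updates.items():
            if k not in vals:
                raise KeyError(f"unknown parameter: {k!r}")
            vals[k] = v
        return ParameterSet(vals, catalog=self.catalog)

    def to_dict(self) -> dict[str, float]:
        return dict(self._resolved)
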