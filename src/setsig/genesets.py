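"""Gene sets, GMT-backed gene-set libraries, and ortholog mapping.

Gene symbols are case-folded to uppercase on ingestion (human-symbol
convention); libraries preserve file order so that downstream rankings are
deterministic.  The GMT dialect is the common tab-separated one: set name,
free-text description (ignored analytically), then one gene per field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetLibrary",
    "OrthologTable",
    "GMTParseError",
    "normalize_symbols",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "map_orthologs",
]


class GMTParseError(ValueError):
    """Raised for malformed GMT / gene-list / ortholog-table input."""


def normalize_symbols(raw: Iterable[str]) -> frozenset[str]:
    """Normalize raw gene identifiers to a deduplicated uppercase set.

    Strips surrounding whitespace, uppercases, and drops empty strings.
    Idempotent: ``normalize_symbols(normalize_symbols(x)) == normalize_symbols(x)``.
    """
    return frozenset(s.strip().upper() for s in raw if s.strip())


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty collection of normalized gene symbols."""

    name: str
    description: str = ""
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet requires a non-empty name")
        if not self.genes:
            raise ValueError(f"GeneSet {self.name!r} has no genes")
        bad = [g for g in self.genes if not g or any(ch.isspace() for ch in g)]
        if bad:
            raise ValueError(
                f"GeneSet {self.name!r} contains symbols with whitespace: {sorted(bad)[:5]}"
            )
        object.__setattr__(self, "genes", frozenset(self.genes))

    @classmethod
    def from_symbols(
        cls, name: str, raw: Iterable[str], description: str = ""
    ) -> "GeneSet":
        """Build a GeneSet from raw (unnormalized) symbols."""
        return cls(name=name, description=description, genes=normalize_symbols(raw))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes


@dataclass
class GeneSetLibrary:
    """Ordered, named collection of GeneSets with unique set names."""

    name: str
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set names in library {self.name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def get(self, set_name: str) -> GeneSet:
        for s in self.sets:
            if s.name == set_name:
                return s
        raise KeyError(set_name)

    @property
    def set_names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT file into a :class:`GeneSetLibrary`.

    Each line must have at least three tab-separated fields
    (name, description, gene, ...).  Empty gene fields are dropped and
    symbols normalized.  Duplicate set names are an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_name, description = fields[0].strip(), fields[1]
            if set_name in seen:
                raise GMTParseError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            seen.add(set_name)
            genes = normalize_symbols(fields[2:])
            if not genes:
                raise GMTParseError(f"{path}:{lineno}: set {set_name!r} has no genes")
            sets.append(GeneSet(name=set_name, description=description, genes=genes))
    return GeneSetLibrary(name=name or path.stem, sets=sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library as GMT with genes sorted lexicographically (deterministic)."""
    if not library.sets:
        raise ValueError("refusing to write an empty library")
    path = Path(path)
    with path.open("w") as fh:
        for s in library.sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line text file as a GeneSet."""
    path = Path(path)
    symbols = path.read_text().splitlines()
    genes = normalize_symbols(symbols)
    if not genes:
        raise GMTParseError(f"{path}: no gene symbols found")
    return GeneSet(name=name or path.stem, genes=genes)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(normalize_symbols(genes))) + "\n")


@dataclass
class OrthologTable:
    """Multimap source symbol -> one or more target symbols.

    One-to-many orthology expands to all targets and deduplicates downstream,
    matching the set-union semantics of enrichment analysis.
    """

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.mapping = {
            src.strip().upper(): normalize_symbols(targets)
            for src, targets in self.mapping.items()
        }

    def __len__(self) -> int:
        return len(self.mapping)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologTable":
        m: dict[str, set[str]] = {}
        for src, tgt in pairs:
            m.setdefault(src.strip().upper(), set()).add(tgt)
        return cls({k: frozenset(normalize_symbols(v)) for k, v in m.items()})

    @classmethod
    def read_tsv(cls, path: str | Path, header: bool = False) -> "OrthologTable":
        """Read a 2-column TSV (source<TAB>target, one pair per line)."""
        path = Path(path)
        pairs: list[tuple[str, str]] = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if header and lineno == 1:
                    continue
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise GMTParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                pairs.append((fields[0], fields[1]))
        if not pairs:
            raise GMTParseError(f"{path}: empty ortholog table")
        return cls.from_pairs(pairs)


def map_orthologs(
    genes: Iterable[str], table: OrthologTable
) -> tuple[frozenset[str], int]:
    """Map symbols through an ortholog table.

    Returns the union of all target symbols of mapped sources, and the count
    of sources with no entry in the table (logged, not fatal).
    """
    if not table.mapping:
        raise ValueError("ortholog table is empty")
    mapped: set[str] = set()
    n_unmapped = 0
    for g in normalize_symbols(genes):
        targets = table.mapping.get(g)
        if targets:
            mapped.update(targets)
        else:
            n_unmapped += 1
    if n_unmapped:
        logger.info("map_orthologs: %d source symbols had no ortholog", n_unmapped)
    return frozenset(mapped), n_unmapped
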