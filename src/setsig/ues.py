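"""Upstream Enrichment Signatures (UES) and blast-style signature search.

A UES summarizes which upstream regulators (transcription factors or
chromatin modifiers from a ChIP-derived regulator library) are enriched in a
gene set: each significantly enriched regulator receives −log10(adjusted p),
the scores are max-normalized to [0, 1], and non-significant regulators are
exactly 0.  UES-blast ranks a reference collection of signatures by
Euclidean distance to a query signature, so gene sets governed by similar
upstream programs rank near each other even when the gene lists themselves
barely overlap.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrich import ALPHA, EnrichmentResult, run_ora
from .genesets import GeneSet, GeneSetLibrary

__all__ = [
    "UES",
    "UESReference",
    "BlastHit",
    "significance_scores",
    "normalize_ues",
    "build_ues",
    "ues_blast",
    "euclidean_distance",
]


@dataclass(frozen=True)
class UES:
    """Sparse signature: regulator name -> score in [0, 1].

    Regulators absent from the map are implicitly 0.  When any regulator is
    significant, max-normalization puts the top regulator at exactly 1.
    """

    origin: str
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for reg, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"UES score out of [0,1] for {reg!r}: {s}")
            if s > 0.0:
                clean[reg] = float(s)
        object.__setattr__(self, "scores", clean)

    def __getitem__(self, regulator: str) -> float:
        return self.scores.get(regulator, 0.0)

    def __len__(self) -> int:
        return len(self.scores)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for reg in sorted(self.scores):
                fh.write(f"{reg}\t{self.scores[reg]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, origin: str | None = None) -> "UES":
        path = Path(path)
        scores: dict[str, float] = {}
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            reg, val = line.split("\t")
            scores[reg] = float(val)
        return cls(origin=origin or path.stem, scores=scores)


def significance_scores(
    results: Sequence[EnrichmentResult], alpha: float = ALPHA
) -> dict[str, float]:
    """Raw significance scores: −log10(adjusted p) for significant regulators.

    Regulators with adjusted p < alpha (strict) score −log10(p_adj); all
    others score 0.  An adjusted p of exactly 0 is clamped to the smallest
    positive float before the log, with a warning.
    """
    scores: dict[str, float] = {}
    for r in results:
        if r.p_adj < alpha:
            p = r.p_adj
            if p == 0.0:
                p = np.nextafter(0.0, 1.0)
                warnings.warn(
                    f"adjusted p of 0 for {r.query_name!r} clamped to {p:g} before log",
                    RuntimeWarning,
                    stacklevel=2,
                )
            scores[r.query_name] = -math.log10(p)
        else:
            scores[r.query_name] = 0.0
    return scores


def normalize_ues(raw: Mapping[str, float], origin: str = "") -> UES:
    """Max-normalize raw scores to [0, 1].

    Division by the maximum maps the top regulator to 1 and keeps
    non-significant regulators at exactly 0 (min-max scaling would conflate
    the weakest significant regulator with the non-significant ones).
    All-zero input is returned unchanged.
    """
    if any(v < 0 for v in raw.values()):
        raise ValueError("raw significance scores must be >= 0")
    top = max(raw.values(), default=0.0)
    if top == 0.0:
        return UES(origin=origin, scores={})
    return UES(origin=origin, scores={k: v / top for k, v in raw.items()})


def build_ues(
    test: GeneSet,
    regulator_library: GeneSetLibrary,
    universe_size: int,
    method: str = "bh",
    alpha: float = ALPHA,
) -> UES:
    """ORA against a regulator library, then score and normalize."""
    results = run_ora(test, regulator_library, universe_size, method=method)
    return normalize_ues(significance_scores(results, alpha=alpha), origin=test.name)


@dataclass
class UESReference:
    """Collection of UES entries with unique origins, plus provenance notes."""

    entries: list[UES]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        origins = [u.origin for u in self.entries]
        if len(origins) != len(set(origins)):
            raise ValueError("UESReference origins must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def write_dir(self, directory: str | Path) -> None:
        """Serialize as a directory of per-origin TSV files plus a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = {}
        for i, u in enumerate(self.entries):
            fname = f"ues_{i:05d}.tsv"
            u.to_tsv(directory / fname)
            files[u.origin] = fname
        manifest = {"provenance": self.provenance, "files": files}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read_dir(cls, directory: str | Path) -> "UESReference":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        entries = [
            UES.from_tsv(directory / fname, origin=origin)
            for origin, fname in manifest["files"].items()
        ]
        return cls(entries=entries, provenance=manifest.get("provenance", {}))

    @classmethod
    def build(
        cls,
        gene_sets: Iterable[GeneSet],
        regulator_library: GeneSetLibrary,
        universe_size: int,
        method: str = "bh",
        alpha: float = ALPHA,
        min_genes: int = 0,
    ) -> "UESReference":
        """Build a reference by running ORA per gene set.

        ``min_genes`` filters out small sets before analysis (the size
        filters used when assembling disease-library references, e.g. >=500
        or >=250 genes, guard against unstable signatures from tiny sets).
        """
        entries = [
            build_ues(gs, regulator_library, universe_size, method=method, alpha=alpha)
            for gs in gene_sets
            if len(gs) >= min_genes
        ]
        return cls(
            entries=entries,
            provenance={"min_genes": min_genes, "method": method, "alpha": alpha},
        )


@dataclass(frozen=True)
class BlastHit:
    """One ranked reference entry: ascending distance, ties by origin."""

    origin: str
    distance: float
    rank: int


def euclidean_distance(x: UES, y: UES) -> float:
    """Euclidean distance over the union of regulator names (missing -> 0)."""
    keys = set(x.scores) | set(y.scores)
    return math.sqrt(sum((x[k] - y[k]) ** 2 for k in keys))


def ues_blast(
    query: UES, reference: UESReference, exclude_origin: bool = False
) -> list[BlastHit]:
    """Rank all reference entries by Euclidean distance to the query.

    Hits are sorted ascending by distance, ties broken lexicographically by
    origin, and assigned ranks 1..n.  ``exclude_origin`` drops reference
    entries whose origin equals the query's (self-matches).
    """
    if len(reference) == 0:
        raise ValueError("reference is empty")
    entries = [
        u for u in reference.entries if not (exclude_origin and u.origin == query.origin)
    ]
    scored = sorted(
        ((euclidean_distance(query, u), u.origin) for u in entries),
        key=lambda t: (t[0], t[1]),
    )
    return [
        BlastHit(origin=origin, distance=dist, rank=i + 1)
        for i, (dist, origin) in enumerate(scored)
    ]
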