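"""Genomic-interval overlap, peak-to-gene assignment, and conditioned ORA.

Coordinates follow the BED convention throughout: 0-based, half-open,
so [100, 200) and [200, 300) do not overlap and the minimum overlap is 1 bp.
Peaks are strandless; genes carry strand, and promoter windows are defined
strand-aware around the TSS (default −1000/+500 bp).  The conditioning
operation compares enrichment of genes targeted by all peaks of a set
against genes targeted only by the subset of peaks co-bound by a second
factor — the readout for asking whether co-bound sites are the ones carrying
a disease-gene signal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable, Sequence

from intervaltree import IntervalTree

from .enrich import EnrichmentResult, run_ora
from .genesets import GeneSetLibrary, normalize_symbols

__all__ = [
    "Peak",
    "PeakSet",
    "GeneModel",
    "OverlapResult",
    "read_bed",
    "read_narrowpeak",
    "write_bed",
    "read_genes_bed6",
    "overlap_peaks",
    "venn_counts",
    "cobound_anchor_fraction",
    "peaks_to_genes",
    "overlap_conditioned_enrichment",
]


class BedParseError(ValueError):
    """Malformed BED/narrowPeak input."""


@dataclass(frozen=True, order=True)
class Peak:
    """One strandless interval; extra BED columns kept opaque."""

    chrom: str
    start: int
    end: int
    extra: tuple = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class PeakSet:
    """Sorted set of strandless half-open genomic intervals."""

    name: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees (half-open, matching BED semantics)."""
        by_chrom: dict[str, IntervalTree] = {}
        for p in self.peaks:
            by_chrom.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
        return by_chrom


@dataclass
class OverlapResult:
    """Peaks of a source set that share >=1 bp with a partner set."""

    source_name: str
    kept: PeakSet
    n_input: int

    @property
    def fraction_overlapping(self) -> float:
        return len(self.kept) / self.n_input if self.n_input else 0.0


def _parse_bed_line(line: str, lineno: int, path: Path, min_fields: int) -> Peak:
    fields = line.split("\t")
    if len(fields) < min_fields:
        raise BedParseError(
            f"{path}:{lineno}: expected >={min_fields} tab-separated columns"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start >= end:
        raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
    return Peak(chrom=chrom, start=start, end=end, extra=tuple(fields[3:]))


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a BED3+ file; output is sorted and validated."""
    return _read_intervals(Path(path), name, min_fields=3)


def read_narrowpeak(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a narrowPeak (BED6+4) file; requires 10 columns."""
    return _read_intervals(Path(path), name, min_fields=10)


def _read_intervals(path: Path, name: str | None, min_fields: int) -> PeakSet:
    peaks = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            peaks.append(_parse_bed_line(line, lineno, path, min_fields))
    return PeakSet(name=name or path.stem, peaks=peaks)


def write_bed(peakset: PeakSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in peakset:
            fields = [p.chrom, str(p.start), str(p.end), *p.extra]
            fh.write("\t".join(fields) + "\n")


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int
    end: int
    name: str
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GeneModel:
    """Gene records (chrom, start, end, name, strand) with unique names."""

    records: list[GeneRecord]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            raise ValueError("gene names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_genes_bed6(path: str | Path) -> GeneModel:
    """Read a gene model from BED6 (chrom, start, end, name, score, strand)."""
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: BED6 requires 6 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            records.append(
                GeneRecord(
                    chrom=fields[0], start=start, end=end,
                    name=fields[3], strand=fields[5],
                )
            )
    return GeneModel(records=records)


def write_genes_bed6(genes: GeneModel, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def overlap_peaks(a: PeakSet, b: PeakSet) -> OverlapResult:
    """Peaks of ``a`` sharing at least 1 bp with any peak of ``b``.

    Half-open semantics: bookended intervals ([100,200) vs [200,300)) do not
    overlap.
    """
    trees = b.trees()
    kept = [
        p for p in a
        if p.chrom in trees and trees[p.chrom].overlaps(p.start, p.end)
    ]
    return OverlapResult(
        source_name=a.name,
        kept=PeakSet(name=f"{a.name}_overlap_{b.name}", peaks=kept),
        n_input=len(a),
    )


def venn_counts(
    sets: Sequence[PeakSet], anchor: PeakSet | None = None
) -> Counter[tuple[str, ...]]:
    """Classify every peak of every set by which sets it overlaps.

    Each peak of each input set contributes one count to the signature of
    set names it overlaps (always including its own set; including the
    anchor's name when an anchor is given).  Identical sets therefore
    populate only the all-present signature, fully disjoint sets only the
    singletons.
    """
    if len(sets) < 2:
        raise ValueError("venn_counts needs at least two peak sets")
    names = [s.name for s in sets]
    if len(names) != len(set(names)):
        raise ValueError("peak-set names must be unique")
    others = list(sets) + ([anchor] if anchor is not None else [])
    trees = {s.name: s.trees() for s in others}
    counts: Counter[tuple[str, ...]] = Counter()
    for s in sets:
        for p in s:
            sig = tuple(
                o.name for o in others
                if o.name == s.name
                or (p.chrom in trees[o.name] and trees[o.name][p.chrom].overlaps(p.start, p.end))
            )
            counts[sig] += 1
    return counts


def cobound_anchor_fraction(sets: Sequence[PeakSet], anchor: PeakSet) -> float:
    """Of the peaks co-bound by *all* input sets, the fraction also
    overlapping the anchor set."""
    counts = venn_counts(sets, anchor=anchor)
    all_names = {s.name for s in sets}
    cobound = sum(n for sig, n in counts.items() if all_names <= set(sig))
    with_anchor = sum(
        n for sig, n in counts.items()
        if all_names <= set(sig) and anchor.name in sig
    )
    return with_anchor / cobound if cobound else 0.0


def peaks_to_genes(
    peaks: PeakSet,
    genes: GeneModel,
    promoter_up: int = 1000,
    promoter_down: int = 500,
    include_body: bool = False,
) -> frozenset[str]:
    """Genes whose promoter (or body) is hit by at least one peak.

    The promoter window runs from ``promoter_up`` bp upstream to
    ``promoter_down`` bp downstream of the TSS, strand-aware: a + strand
    gene with TSS t gets [t−up, t+down); a − strand gene with TSS t gets
    [t−down, t+up).  A gene overlapping both promoter and body is counted
    once.  Returns the (possibly empty) deduplicated set of gene symbols.
    """
    if len(genes) == 0:
        raise ValueError("gene model is empty")
    trees = peaks.trees()
    hit: set[str] = set()
    for g in genes:
        if g.chrom not in trees:
            continue
        tree = trees[g.chrom]
        if g.strand == "+":
            prom = (g.tss - promoter_up, g.tss + promoter_down)
        else:
            prom = (g.tss - promoter_down, g.tss + promoter_up)
        windows = [prom]
        if include_body:
            windows.append((g.start, g.end))
        for lo, hi in windows:
            if tree.overlaps(max(lo, 0), hi):
                hit.add(g.name)
                break
    return frozenset(normalize_symbols(hit))


def overlap_conditioned_enrichment(
    a: PeakSet,
    b: PeakSet,
    genes: GeneModel,
    query_library: GeneSetLibrary,
    universe_size: int,
    method: str = "bonferroni",
    promoter_up: int = 1000,
    promoter_down: int = 500,
    include_body: bool = False,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Paired ORA: genes of all ``a`` peaks vs genes of a∩b peaks only.

    Returns (unconditioned, conditioned) result lists in library order, so
    the i-th entries of both refer to the same query set.
    """
    kept = overlap_peaks(a, b).kept
    kwargs = dict(
        promoter_up=promoter_up, promoter_down=promoter_down, include_body=include_body
    )
    genes_all = peaks_to_genes(a, genes, **kwargs)
    genes_cond = peaks_to_genes(kept, genes, **kwargs)
    uncond = run_ora(genes_all, query_library, universe_size, method=method, sort=False)
    cond = run_ora(genes_cond, query_library, universe_size, method=method, sort=False)
    return uncond, cond
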