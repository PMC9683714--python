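"""One-sided Fisher over-representation analysis (ORA).

Tests whether a query gene set overlaps a test gene list more than expected
under the hypergeometric null, with multiple-testing adjustment across the
library, cross-product odds ratios, and a permutation null distribution of
odds ratios for calibrating observed enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, GeneSetLibrary

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "NullDistribution",
    "contingency_table",
    "fisher_one_sided",
    "odds_ratio",
    "adjust_pvalues",
    "run_ora",
    "null_odds_distribution",
    "empirical_p",
    "results_to_frame",
]

#: significance threshold on adjusted p used throughout (strict inequality)
ALPHA = 0.05


class UniverseError(ValueError):
    """Universe size inconsistent with the observed sets."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for one test-set / query-set pair over a gene universe.

    a: in test and in query; b: in test only; c: in query only;
    d: in neither.  a+b+c+d equals the universe size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError(f"cells must be nonnegative integers, got {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency_table(
    test: GeneSet | Collection[str],
    query: GeneSet | Collection[str],
    universe_size: int,
    universe: GeneSet | Collection[str] | None = None,
) -> ContingencyTable:
    """Build the 2x2 table for a test list against a query set.

    When an explicit ``universe`` collection is supplied, both sets are
    intersected with it and its size overrides ``universe_size``; otherwise
    the declared size is trusted (size-only mode).
    """
    t = _as_symbols(test)
    q = _as_symbols(query)
    if universe is not None:
        u = _as_symbols(universe)
        t, q = t & u, q & u
        universe_size = len(u)
    a = len(t & q)
    b = len(t) - a
    c = len(q) - a
    d = universe_size - a - b - c
    if d < 0:
        raise UniverseError(
            f"universe_size={universe_size} smaller than |test ∪ query|={a + b + c}"
        )
    return ContingencyTable(a, b, c, d)


def _as_symbols(obj: GeneSet | Collection[str]) -> frozenset[str]:
    if isinstance(obj, GeneSet):
        return obj.genes
    return frozenset(obj)


def fisher_one_sided(table: ContingencyTable) -> float:
    """Exact one-sided (enrichment) Fisher p-value, P(X >= a).

    X is hypergeometric with the table's margins: population a+b+c+d,
    a+b successes (the test list), a+c draws (the query set).  Exact tail
    probability, not a normal approximation.
    """
    return float(hypergeom.sf(table.a - 1, table.n, table.a + table.b, table.a + table.c))


def odds_ratio(table: ContingencyTable) -> float:
    """Sample (cross-product) odds ratio (a·d)/(b·c).

    When any cell is zero the Haldane–Anscombe correction adds 0.5 to every
    cell, keeping the estimate finite and monotone.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def adjust_pvalues(
    pvals: Sequence[float], method: str = "bonferroni"
) -> list[float]:
    """Multiple-testing adjustment, preserving input order.

    ``bonferroni``: min(1, m·p).  ``bh``: Benjamini–Hochberg step-up,
    monotone and capped at 1.
    """
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}
    if method not in key:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, adj, _, _ = multipletests(arr, method=key[method])
    return [float(p) for p in adj]


@dataclass(frozen=True)
class EnrichmentResult:
    """ORA result for one query set: 2x2 cells, p, adjusted p, odds ratio."""

    query_name: str
    table: ContingencyTable
    p: float
    p_adj: float
    odds_ratio: float


def run_ora(
    test: GeneSet | Collection[str],
    library: GeneSetLibrary,
    universe_size: int,
    method: str = "bonferroni",
    universe: GeneSet | Collection[str] | None = None,
    sort: bool = True,
) -> list[EnrichmentResult]:
    """ORA of a test gene list against every set of a library.

    Adjusted p-values are computed across the whole library (family size =
    number of sets tested).  Results are sorted by (p_adj, p, query name)
    unless ``sort=False``, which preserves library order (useful for pairing
    two runs set-by-set).
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    tables = [
        contingency_table(test, qs, universe_size, universe=universe)
        for qs in library
    ]
    # vectorized hypergeometric survival function across the library
    a = np.array([t.a for t in tables])
    n = np.array([t.n for t in tables])
    t_sz = np.array([t.a + t.b for t in tables])
    q_sz = np.array([t.a + t.c for t in tables])
    pvals = hypergeom.sf(a - 1, n, t_sz, q_sz)
    p_adj = adjust_pvalues(pvals.tolist(), method=method)
    results = [
        EnrichmentResult(
            query_name=qs.name,
            table=tbl,
            p=float(p),
            p_adj=pa,
            odds_ratio=odds_ratio(tbl),
        )
        for qs, tbl, p, pa in zip(library, tables, pvals, p_adj)
    ]
    if sort:
        results.sort(key=lambda r: (r.p_adj, r.p, r.query_name))
    return results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results (query_name, a, b, c, d, odds_ratio, p, p_adj)."""
    rows = [
        {
            "query_name": r.query_name,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "odds_ratio": r.odds_ratio,
            "p": r.p,
            "p_adj": r.p_adj,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


@dataclass
class NullDistribution:
    """Permutation null of odds ratios: random draws of size k vs a query set."""

    draws: np.ndarray
    k: int
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.shape != (self.n_perm,):
            raise ValueError("draws length must equal n_perm")

    @property
    def median(self) -> float:
        return float(np.median(self.draws))


def null_odds_distribution(
    query: GeneSet | Collection[str],
    universe: GeneSet | Collection[str],
    k: int,
    n_perm: int,
    seed: int,
) -> NullDistribution:
    """Null distribution of odds ratios from random gene lists.

    Each permutation draws ``k`` genes without replacement from the universe
    and records the cross-product odds ratio of that draw against ``query``
    over the same universe.  Reproducible given ``seed``.
    """
    uni = sorted(_as_symbols(universe))
    n_universe = len(uni)
    if k > n_universe:
        raise ValueError(f"k={k} exceeds universe size {n_universe}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    q = _as_symbols(query) & set(uni)
    q_mask = np.fromiter((g in q for g in uni), dtype=bool, count=n_universe)
    n_query = int(q_mask.sum())
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        idx = rng.choice(n_universe, size=k, replace=False)
        a = int(q_mask[idx].sum())
        tbl = ContingencyTable(a, k - a, n_query - a, n_universe - k - n_query + a)
        draws[i] = odds_ratio(tbl)
    return NullDistribution(draws=draws, k=k, n_perm=n_perm, seed=seed)


def empirical_p(observed: float, null: NullDistribution) -> float:
    """Add-one empirical p-value: (1 + #{draws >= observed}) / (n_perm + 1).

    Ties count toward the tail; the +1 estimator never returns zero.
    """
    if null.n_perm < 1:
        raise ValueError("null distribution is empty")
    return float((1 + int(np.sum(null.draws >= observed))) / (null.n_perm + 1))
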