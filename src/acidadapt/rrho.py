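"""Rank-rank hypergeometric overlap (RRHO) between two ranked gene lists.

Two gene lists over the same universe are each ranked by a score (log2
fold change, most upregulated first).  For every pair of rank thresholds
(i, j) on a regular grid, the overlap k between the top-i genes of one
list and the top-j genes of the other is tested against the hypergeometric
null of independent rankings; the matrix of window p-values is the RRHO
map.  A patient whose tumor-vs-normal ranking shares the acid-adaptation
ordering lights up the co-upregulation corner of the map.

The similarity score of a comparison is the fraction of windows whose
over-enrichment p-value falls below ``alpha`` (0.05); a comparison with
similarity strictly above ``high_threshold`` (0.20) is classified as high
similarity.  The default grid is 10 x 10 (step = floor(N / 10)), i.e. 100
windows, and window p-values are used raw, without multiplicity
correction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

DEFAULT_ALPHA = 0.05
DEFAULT_HIGH_THRESHOLD = 0.20
DEFAULT_MIN_OCCURRENCE = 50


@dataclass(frozen=True)
class RankedGeneList:
    """Genes totally ordered by non-increasing score."""

    gene_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "scores", scores)
        if gene_ids.shape != scores.shape or gene_ids.ndim != 1:
            raise ValueError("gene_ids and scores must be 1-D and of equal length")
        if len(gene_ids) < 2:
            raise ValueError("a ranked list needs at least 2 genes")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> set:
        return set(self.gene_ids[:k])


def make_ranked_list(scores: Mapping[str, float] | pd.Series) -> RankedGeneList:
    """Rank genes by descending score; ties broken by lexicographic gene id."""
    series = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    if series.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if len(series) < 2:
        raise ValueError("need at least 2 genes")
    if not np.all(np.isfinite(series.to_numpy(dtype=float))):
        raise ValueError("scores must be finite")
    ordered = series.sort_index().sort_values(ascending=False, kind="stable")
    return RankedGeneList(ordered.index.to_numpy(dtype=object), ordered.to_numpy(dtype=float))


def harmonize_universe(
    list_a: RankedGeneList, list_b: RankedGeneList, min_size: int = 4
) -> tuple[RankedGeneList, RankedGeneList]:
    """Restrict both lists to the shared gene universe and re-rank each."""
    shared = set(list_a.gene_ids) & set(list_b.gene_ids)
    if len(shared) < min_size:
        raise ValueError(
            f"shared universe has {len(shared)} genes "
            f"(lists of {len(list_a)} and {len(list_b)}); need >= {min_size}"
        )

    def _restrict(lst: RankedGeneList) -> RankedGeneList:
        keep = np.array([g in shared for g in lst.gene_ids])
        return make_ranked_list(pd.Series(lst.scores[keep], index=lst.gene_ids[keep]))

    return _restrict(list_a), _restrict(list_b)


def _log_hypergeom_pmf_terms(N: int, K: int, n: int, xs: np.ndarray) -> np.ndarray:
    """log P(X = x) for X ~ Hypergeometric(N, K, n) at each x in xs."""
    xs = np.asarray(xs, dtype=float)
    return (
        gammaln(K + 1) - gammaln(xs + 1) - gammaln(K - xs + 1)
        + gammaln(N - K + 1) - gammaln(n - xs + 1) - gammaln(N - K - n + xs + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def _log_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """log P(X >= k), summed in log space for stability."""
    lo = max(0, n + K - N)
    hi = min(K, n)
    if k <= lo:
        return 0.0
    xs = np.arange(k, hi + 1)
    return min(0.0, float(logsumexp(_log_hypergeom_pmf_terms(N, K, n, xs))))


def _log_lower_tail(N: int, K: int, n: int, k: int) -> float:
    """log P(X <= k)."""
    lo = max(0, n + K - N)
    hi = min(K, n)
    if k >= hi:
        return 0.0
    xs = np.arange(lo, k + 1)
    return min(0.0, float(logsumexp(_log_hypergeom_pmf_terms(N, K, n, xs))))


def hypergeom_overlap_p(N: int, i: int, j: int, k: int) -> float:
    """Over-enrichment tail P(X >= k) for the overlap of top-i and top-j.

    X is hypergeometric with population N, j successes and i draws (the
    tail is symmetric in i and j).
    """
    if not (0 <= k <= min(i, j) <= N):
        raise ValueError(f"infeasible overlap: N={N}, i={i}, j={j}, k={k}")
    if k < max(0, i + j - N):
        raise ValueError(f"overlap k={k} below the feasible minimum {max(0, i + j - N)}")
    return float(np.exp(_log_upper_tail(N, j, i, k)))


@dataclass
class RRHOResult:
    """Window matrices and (once scored) similarity of one comparison."""

    step: int
    grid: np.ndarray  # rank thresholds s, 2s, ..., m*s
    raw_p: np.ndarray  # over-enrichment tail per window
    signed_log_p: np.ndarray  # -log10 p (over-enriched) / +log10 p_under (negative)
    overlap_counts: np.ndarray
    n_genes: int
    similarity: float | None = None
    is_high_similarity: bool | None = None
    overlap_genes: frozenset | None = None


def rrho_matrix(
    list_a: RankedGeneList, list_b: RankedGeneList, step: int | None = None
) -> RRHOResult:
    """Exact RRHO window matrices between two harmonized ranked lists.

    ``step`` defaults to floor(N / 10), which tiles the rank space into a
    10 x 10 grid of 100 windows.
    """
    if set(list_a.gene_ids) != set(list_b.gene_ids):
        raise ValueError("lists must share one universe; call harmonize_universe first")
    N = len(list_a)
    if step is None:
        step = max(1, N // 10)
    if not 1 <= step <= N // 2:
        raise ValueError(f"step must be in [1, N/2]; got {step} with N={N}")
    m = N // step
    grid = step * np.arange(1, m + 1)

    rank_in_b = {g: r for r, g in enumerate(list_b.gene_ids, start=1)}
    b_ranks_in_a_order = np.array([rank_in_b[g] for g in list_a.gene_ids])

    overlap = np.empty((m, m), dtype=np.int64)
    for gi, i in enumerate(grid):
        prefix = np.sort(b_ranks_in_a_order[:i])
        overlap[gi, :] = np.searchsorted(prefix, grid, side="right")

    raw_p = np.empty((m, m))
    signed = np.empty((m, m))
    for gi, i in enumerate(grid):
        for gj, j in enumerate(grid):
            k = int(overlap[gi, gj])
            log_over = _log_upper_tail(N, int(j), int(i), k)
            raw_p[gi, gj] = np.exp(log_over)
            if k * N >= i * j:  # at or above expectation -> over-enriched
                signed[gi, gj] = -log_over / np.log(10.0)
            else:
                signed[gi, gj] = _log_lower_tail(N, int(j), int(i), k) / np.log(10.0)
    return RRHOResult(
        step=int(step), grid=grid, raw_p=raw_p, signed_log_p=signed,
        overlap_counts=overlap, n_genes=N,
    )


def similarity_score(
    result: RRHOResult,
    alpha: float = DEFAULT_ALPHA,
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
) -> tuple[float, bool]:
    """Fraction of windows with p < alpha; high similarity iff strictly > threshold."""
    if result.raw_p.size == 0:
        raise ValueError("empty window matrix")
    similarity = float(np.mean(result.raw_p < alpha))
    is_high = bool(similarity > high_threshold)
    result.similarity = similarity
    result.is_high_similarity = is_high
    return similarity, is_high


def extract_overlap_genes(
    result: RRHOResult,
    list_a: RankedGeneList,
    list_b: RankedGeneList,
    alpha: float = DEFAULT_ALPHA,
) -> frozenset:
    """Union of top-segment intersections over significant over-enriched windows."""
    genes: set = set()
    m = len(result.grid)
    for gi in range(m):
        i = int(result.grid[gi])
        for gj in range(m):
            j = int(result.grid[gj])
            k = int(result.overlap_counts[gi, gj])
            if result.raw_p[gi, gj] < alpha and k * result.n_genes >= i * j:
                genes |= list_a.top(i) & list_b.top(j)
    out = frozenset(genes)
    result.overlap_genes = out
    return out


@dataclass(frozen=True)
class OccurrenceTable:
    """Per-gene multiplicity across a collection of overlap gene sets."""

    counts: pd.Series  # gene_id -> number of comparisons containing it
    total_comparisons: int


def occurrence_counts(overlap_sets: Iterable[Iterable[str]]) -> OccurrenceTable:
    sets = [set(s) for s in overlap_sets]
    if not sets:
        raise ValueError("need at least one comparison")
    counter: Counter = Counter()
    for s in sets:
        counter.update(s)
    counts = pd.Series(dict(counter), dtype=int).sort_index()
    counts.index.name = "gene_id"
    return OccurrenceTable(counts=counts, total_comparisons=len(sets))


def threshold_filter(table: OccurrenceTable, min_occurrence: int = DEFAULT_MIN_OCCURRENCE) -> frozenset:
    """Genes appearing in at least ``min_occurrence`` comparisons."""
    return frozenset(table.counts.index[table.counts >= min_occurrence])
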