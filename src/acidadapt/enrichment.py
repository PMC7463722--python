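"""Over-representation analysis and preranked gene-set enrichment.

``ora_test`` applies the hypergeometric over-enrichment tail to each set
of a GMT-style collection against an expressed-gene background, with
Benjamini-Hochberg adjustment across the collection.

``gsea_preranked`` walks the ranked gene list accumulating a running sum:
gene-set members (hits) add their score magnitude raised to
``weight_exponent`` (normalized over hits), non-members subtract
1/(N - n_hits).  The enrichment score (ES) is the extreme deviation of
the running sum; significance comes from gene-label permutations of the
set, and the normalized ES divides the observed ES by the mean magnitude
of same-sign permutation scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from acidadapt.de import benjamini_hochberg
from acidadapt.rrho import RankedGeneList, hypergeom_overlap_p

DEFAULT_WEIGHT_EXPONENT = 1.0
DEFAULT_N_PERMUTATIONS = 1000


def ora_test(
    query: set,
    universe: set,
    collection: dict[str, set],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection set.

    All sets are intersected with the universe before testing; sets that
    do not intersect the universe are skipped with a warning.  Returns a
    DataFrame with columns set_name, set_size, overlap, p_value, fdr.
    """
    query = set(query)
    universe = set(universe)
    offenders = query - universe
    if offenders:
        raise ValueError(f"query genes outside the universe: {sorted(offenders)[:10]}")
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        if not members:
            warnings.warn(f"gene set {name!r} is disjoint from the universe; skipped")
            continue
        k = len(members & query)
        p = hypergeom_overlap_p(len(universe), len(query), len(members), k)
        rows.append({"set_name": name, "set_size": len(members), "overlap": k, "p_value": p})
    result = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    result["fdr"] = benjamini_hochberg(result["p_value"].to_numpy()) if len(result) else pd.Series(dtype=float)
    return result


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    set_size: int
    es: float
    nes: float  # NaN when no same-sign permutation score exists
    perm_p: float
    n_perm: int
    running_sum: np.ndarray
    hit_positions: np.ndarray


def _enrichment_score(
    hit_mask: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """ES and running sum for one hit configuration.

    ``weights`` are the per-position increments already normalized so hits
    sum to 1; misses each decrement 1/(N - n_hits).
    """
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    miss_dec = 1.0 / (n - n_hits)
    steps = np.where(hit_mask, weights, -miss_dec)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def gsea_preranked(
    ranked: RankedGeneList,
    gene_set: set,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    set_name: str = "gene_set",
) -> GseaResult:
    """Preranked GSEA of one gene set against a ranked list.

    The permutation p-value is the one-sided frequency of same-sign null
    enrichment scores at least as extreme as the observed one.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = ranked.gene_ids
    n = len(genes)
    hit_mask = np.array([g in gene_set for g in genes])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole list; miss decrement undefined")

    mags = np.abs(ranked.scores) ** weight_exponent

    def weights_for(mask: np.ndarray) -> np.ndarray:
        total = mags[mask].sum()
        if total == 0:  # all hit scores zero: fall back to equal increments
            w = np.zeros(n)
            w[mask] = 1.0 / mask.sum()
            return w
        w = np.zeros(n)
        w[mask] = mags[mask] / total
        return w

    es, running = _enrichment_score(hit_mask, weights_for(hit_mask))

    null_es = np.empty(n_perm)
    for b in range(n_perm):
        perm_idx = rng.choice(n, size=n_hits, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[perm_idx] = True
        null_es[b], _ = _enrichment_score(mask, weights_for(mask))

    same_sign = null_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, dtype=bool)
    n_same = int(same_sign.sum())
    if n_same == 0:
        perm_p, nes = 1.0, float("nan")
    else:
        perm_p = float(np.sum(np.abs(null_es[same_sign]) >= abs(es)) / n_same)
        nes = float(es / np.mean(np.abs(null_es[same_sign])))
    return GseaResult(
        set_name=set_name,
        set_size=n_hits,
        es=es,
        nes=nes,
        perm_p=perm_p,
        n_perm=n_perm,
        running_sum=running,
        hit_positions=np.flatnonzero(hit_mask),
    )
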