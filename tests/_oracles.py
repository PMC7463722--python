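"""Independent brute-force reference implementations used only by tests.

Each oracle is written in the most literal way possible (exact rational
arithmetic, explicit loops) so it shares no code path with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hypergeom_upper_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return Fraction(total, denom)


def overlap_p_by_enumeration(list_a, list_b, i: int, j: int) -> Fraction:
    """RRHO window p by direct set intersection + combinatorial sum."""
    top_a = set(list_a[:i])
    top_b = set(list_b[:j])
    k = len(top_a & top_b)
    return hypergeom_upper_tail_exact(len(list_a), j, i, k)


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg by the literal definition q_(i) = min_{j>=i} p_(j) m / j."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda idx: p[idx])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[jj - 1]] * m / jj for jj in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return np.array(q)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p: sum of fixed-margin tables with prob <= observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = math.comb(N, c1)

    def table_weight(x: int) -> int:
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    observed = table_weight(a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = table_weight(x)
        if w <= observed:
            total += w
    return Fraction(total, denom)


def tmm_factor_bruteforce(counts: np.ndarray, ref_idx: int) -> np.ndarray:
    """TMM factors by literal loops: per-sample trimmed weighted mean of M.

    counts: genes x samples; returns factors with geometric mean 1.
    """
    n_samples = counts.shape[1]
    lib = counts.sum(axis=0)
    log_f = np.zeros(n_samples)
    ref = counts[:, ref_idx].astype(float)
    for s in range(n_samples):
        obs = counts[:, s].astype(float)
        M, A, w = [], [], []
        for g in range(counts.shape[0]):
            if obs[g] > 0 and ref[g] > 0:
                po = obs[g] / lib[s]
                pr = ref[g] / lib[ref_idx]
                M.append(math.log2(po / pr))
                A.append(0.5 * math.log2(po * pr))
                w.append(
                    (lib[s] - obs[g]) / (lib[s] * obs[g])
                    + (lib[ref_idx] - ref[g]) / (lib[ref_idx] * ref[g])
                )
        M, A, w = np.array(M), np.array(A), np.array(w)
        n = len(M)
        # R-style average ranks
        def ranks(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(n)
            i = 0
            sorted_v = v[order]
            while i < n:
                j = i
                while j + 1 < n and sorted_v[j + 1] == sorted_v[i]:
                    j += 1
                r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
                i = j + 1
            return r

        rm, ra = ranks(M), ranks(A)
        lo_m = math.floor(n * 0.3) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
            if not np.isfinite(f) or abs(f) < 1e-6:
                f = 0.0
        else:
            f = 0.0
        log_f[s] = f
    return 2.0 ** (log_f - log_f.mean())


def logrank_bruteforce(times_h, events_h, times_l, events_l):
    """Log-rank chi-square and O-E of the high group by explicit sums."""
    times_h, times_l = np.asarray(times_h, float), np.asarray(times_l, float)
    events_h, events_l = np.asarray(events_h, bool), np.asarray(events_l, bool)
    all_t = np.concatenate([times_h, times_l])
    all_e = np.concatenate([events_h, events_l])
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(all_t[all_e])):
        nh = int((times_h >= t).sum())
        nl = int((times_l >= t).sum())
        n = nh + nl
        d = int(((all_t == t) & all_e).sum())
        dh = int(((times_h == t) & events_h).sum())
        o_minus_e += dh - d * nh / n
        if n > 1:
            var += d * (n - d) * nh * nl / (n * n * (n - 1))
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return chi2, o_minus_e
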