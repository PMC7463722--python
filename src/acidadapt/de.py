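"""Shared differential-expression response across acid-adapted cell lines.

The analysis chain follows the standard count-based workflow: CPM
filtering of weakly expressed genes, trimmed-mean-of-M-values (TMM)
library normalization, log2-CPM transformation, mean-variance precision
weights, and a weighted linear-model fit per gene with empirical-Bayes
shrinkage of the residual variances.  The design matrix contains an
intercept, fixed cell-line blocking factors and the acid-vs-control pH
indicator, whose coefficient is the shared acid-adaptation log2 fold
change.  Genes are called up/down when FDR < ``fdr_threshold`` and the
log2FC clears ``lfc_threshold`` (defaults 0.05 and 0.5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_MIN_CPM = 1.0
DEFAULT_MIN_SAMPLES = 3
DEFAULT_LFC_THRESHOLD = 0.5
DEFAULT_FDR_THRESHOLD = 0.05
LOWESS_SPAN = 0.5


def _as_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers")
    values = counts.to_numpy()
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("counts must be finite and non-negative")
    return counts


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million on raw library sizes."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive total count")
    return counts * 1e6 / lib


def filter_low_counts(
    counts: pd.DataFrame,
    design: pd.DataFrame | None = None,
    min_cpm: float = DEFAULT_MIN_CPM,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> pd.DataFrame:
    """Keep genes with CPM >= min_cpm in at least min_samples samples."""
    counts = _as_count_matrix(counts)
    if min_samples > counts.shape[1]:
        raise ValueError(f"min_samples={min_samples} exceeds {counts.shape[1]} samples")
    if min_cpm <= 0:
        return counts
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "no gene passes the expression filter; relax min_cpm or min_samples"
        )
    return counts.loc[keep]


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, log_ratio_trim: float = 0.3, abs_expr_trim: float = 0.05
) -> float:
    """log2 TMM factor of one sample against the reference sample."""
    lib_obs, lib_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no positively expressed gene with the reference")
    p_obs = obs[both] / lib_obs
    p_ref = ref[both] / lib_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M (delta method on two binomial proportions)
    w = (lib_obs - obs[both]) / (lib_obs * obs[both]) + (lib_ref - ref[both]) / (lib_ref * ref[both])
    n = len(M)
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(M), rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) or abs(f) < 1e-6 else float(f)


def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factor per sample.

    M (log2 ratio) and A (average log2 abundance) are computed on
    library-size-normalized proportions over genes positive in both the
    sample and the reference; the most extreme 30% of M and 5% of A are
    trimmed from each tail, and the factor is 2 to the inverse-variance
    weighted mean of the surviving M values.  Factors are rescaled to a
    geometric mean of 1.  The reference defaults to the sample whose
    75th-percentile CPM is closest to the mean of those percentiles.
    """
    counts = _as_count_matrix(counts)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive total count")
    if ref_sample is None:
        q75 = cpm(counts).quantile(0.75, axis=0)
        ref_sample = (q75 - q75.mean()).abs().idxmin()
    elif ref_sample not in counts.columns:
        raise ValueError(f"unknown reference sample {ref_sample!r}")
    ref = counts[ref_sample].to_numpy(dtype=float)
    log_factors = pd.Series(
        {s: _tmm_pair(counts[s].to_numpy(dtype=float), ref) for s in counts.columns},
        name="tmm_factor",
    )
    factors = np.exp2(log_factors - log_factors.mean())  # geometric mean 1
    return factors


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2 counts-per-million with a 0.5 count offset.

    entry = log2((count + 0.5) / (effective library size + 1) * 1e6),
    effective library size = raw total * TMM factor.
    """
    counts = _as_count_matrix(counts)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("factors must be positive and cover every sample")
    eff_lib = counts.sum(axis=0) * factors
    return np.log2((counts + 0.5) / (eff_lib + 1.0) * 1e6)


def build_design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Intercept + cell-line blocking dummies + acid-pH indicator.

    The pH coefficient (last column) is the shared acid response; cell-line
    terms absorb baseline differences between lines.
    """
    required = {"sample_id", "cell_line", "ph"}
    if not required.issubset(design.columns):
        raise ValueError(f"design needs columns {sorted(required)}")
    ph = design["ph"].astype(str)
    if set(ph.unique()) - {"acid", "control"}:
        raise ValueError("ph must be 'acid' or 'control'")
    if len(ph.unique()) < 2:
        raise ValueError("both pH conditions must be present")
    X = pd.DataFrame({"intercept": 1.0}, index=design["sample_id"])
    lines = sorted(design["cell_line"].astype(str).unique())
    for line in lines[1:]:
        X[f"cell_line[{line}]"] = (design["cell_line"].astype(str) == line).to_numpy(float)
    X["ph[acid]"] = (ph == "acid").to_numpy(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)")
    return X


def precision_weights(
    log_cpm_matrix: pd.DataFrame, design: pd.DataFrame, span: float = LOWESS_SPAN
) -> pd.DataFrame:
    """Mean-variance precision weights for the weighted linear-model fit.

    Per gene, an unweighted fit of the design gives residual standard
    deviations; sqrt(sd) is smoothed against average log-CPM by LOWESS and
    each observation's weight is the inverse fourth power of the trend
    evaluated at its fitted log-CPM (clamped to the trend's range at the
    extremes).
    """
    X = build_design_matrix(design).to_numpy()
    n, p = X.shape
    if n - p < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    Y = log_cpm_matrix.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T  # genes x samples
    resid = Y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    sqrt_sd = np.sqrt(sigma)
    mean_lcpm = Y.mean(axis=1)

    # deterministic tie-break: sort by (abundance, gene id)
    order = np.lexsort((log_cpm_matrix.index.to_numpy(), mean_lcpm))
    smoothed = lowess(
        sqrt_sd[order], mean_lcpm[order], frac=span, it=3, delta=0.01 * np.ptp(mean_lcpm),
        return_sorted=True,
    )
    trend_x, trend_y = smoothed[:, 0], np.maximum(smoothed[:, 1], 1e-6)
    # np.interp clamps to the trend's endpoints outside its range
    trend_at = np.interp(fitted, trend_x, trend_y)
    weights = 1.0 / trend_at**4
    return pd.DataFrame(weights, index=log_cpm_matrix.index, columns=log_cpm_matrix.columns)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df_residual: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Moments of log s_g^2 are matched to those of a log scaled-F deviate to
    estimate the prior degrees of freedom d0 and prior variance s0^2; the
    posterior variance is the df-weighted average of prior and observed.
    If the variance equation has no positive solution, d0 is infinite and
    every posterior variance equals s0^2.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    d = float(df_residual)
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_2 + d * s2) / (d0 + d)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        post = np.full_like(s2, s0_2)
    return d0, s0_2, post


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fit_shared_response(
    log_cpm_matrix: pd.DataFrame,
    weights: pd.DataFrame,
    design: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Weighted per-gene fit with moderated t statistics on the pH coefficient.

    ``prior_df`` overrides the estimated prior degrees of freedom (useful
    to force the full-shrinkage limit); by default it is estimated by
    moment matching on the log residual variances.

    Returns a DataFrame indexed by gene with columns log2fc, avg_log_cpm,
    moderated_t, p_value, fdr, call.
    """
    X_df = build_design_matrix(design)
    X = X_df.to_numpy()
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    Y = log_cpm_matrix.to_numpy(dtype=float)
    W = weights.reindex(index=log_cpm_matrix.index, columns=log_cpm_matrix.columns).to_numpy(float)
    if np.any(~np.isfinite(W)) or np.any(W <= 0):
        raise ValueError("weights must be positive and finite")

    XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
    XtWy = np.einsum("ni,gn,gn->gi", X, W, Y)
    beta = np.linalg.solve(XtWX, XtWy[:, :, None])[:, :, 0]
    resid = Y - beta @ X.T
    rss = np.einsum("gn,gn->g", W, resid**2)
    s2 = rss / df_resid
    unscaled_se = np.sqrt(np.linalg.inv(XtWX)[:, -1, -1])

    if prior_df is None:
        d0, s0_2, post_var = squeeze_variances(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_2, _ = squeeze_variances(s2, df_resid)
        if np.isinf(d0):
            post_var = np.full_like(s2, s0_2)
        else:
            post_var = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)

    log2fc = beta[:, -1]
    t_stat = log2fc / (np.sqrt(post_var) * unscaled_se)
    total_df = df_resid + d0
    if np.isinf(total_df):
        p_value = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p_value = 2.0 * stats.t.sf(np.abs(t_stat), df=total_df)
    fdr = benjamini_hochberg(p_value)
    call = np.where(
        (fdr < fdr_threshold) & (log2fc > lfc_threshold), "up",
        np.where((fdr < fdr_threshold) & (log2fc < -lfc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "avg_log_cpm": Y.mean(axis=1),
            "moderated_t": t_stat,
            "p_value": p_value,
            "fdr": fdr,
            "call": call,
        },
        index=log_cpm_matrix.index,
    )


def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    min_cpm: float = DEFAULT_MIN_CPM,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Filter -> TMM -> log-CPM -> precision weights -> moderated fit."""
    filtered = filter_low_counts(counts, design, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered)
    lcpm = log_cpm(filtered, factors)
    w = precision_weights(lcpm, design)
    return fit_shared_response(
        lcpm, w, design, lfc_threshold=lfc_threshold, fdr_threshold=fdr_threshold
    )
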