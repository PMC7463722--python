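"""Median-split overall-survival screen across cancer cohorts.

For every (gene, cohort) pair, patients are split into high and low
expressors at the cohort median (ties go to the low group), the two
Kaplan-Meier curves are compared by the log-rank test, and the prognosis
direction is read off the sign of the observed-minus-expected death count
in the high-expression group: more deaths than expected means high
expression associates with poorer overall survival.  Per-gene p-values
are reported raw at alpha = 0.05, matching a screen of a few hundred
candidate genes per cohort; a Benjamini-Hochberg column is available as
an optional extension.  Multi-cohort rollups collect genes significant in
at least ``min_cohorts`` cohorts and flag genes whose direction
contradicts itself across cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from acidadapt.de import benjamini_hochberg

ALPHA = 0.05
POOR = "high_expr_poor_os"
BETTER = "high_expr_better_os"
MIN_COHORT_SIZE = 8


def median_split(expression: pd.Series) -> pd.Series:
    """Label patients 'high' (value > median) or 'low' (value <= median)."""
    values = expression.astype(float)
    if len(values) < 4:
        raise ValueError("median split needs at least 4 patients")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    cutoff = float(values.median())
    labels = pd.Series(np.where(values > cutoff, "high", "low"), index=values.index)
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValueError("degenerate gene: one median-split group is empty")
    return labels


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    needed = {"time", "event"}
    if not needed.issubset(records.columns):
        raise ValueError("survival records need 'time' and 'event' columns")
    t = records["time"].astype(float)
    if (t < 0).any() or not np.all(np.isfinite(t)):
        raise ValueError("survival times must be finite and non-negative")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns one row per distinct event time with columns time, n_at_risk,
    n_events, survival.  Censored subjects remain in the risk set through
    their censoring time and leave just after it; S(0) = 1.
    """
    records = _validate_records(records)
    if len(records) == 0:
        raise ValueError("need at least one record")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    out = []
    surv = 1.0
    for time in np.unique(t[e]):
        n_risk = int(np.sum(t >= time))
        d = int(np.sum((t == time) & e))
        surv *= 1.0 - d / n_risk
        out.append((time, n_risk, d, surv))
    return pd.DataFrame(out, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(group_high: pd.DataFrame, group_low: pd.DataFrame) -> tuple[float, float, float]:
    """Two-group log-rank test.

    Returns (chi_square, p_value, o_minus_e_high) where o_minus_e_high is
    the summed observed-minus-expected death count in the high group; a
    positive value means the high group died more than expected.
    """
    group_high = _validate_records(group_high)
    group_low = _validate_records(group_low)
    if len(group_high) == 0 or len(group_low) == 0:
        raise ValueError("both groups must be non-empty")
    th, eh = group_high["time"].to_numpy(float), group_high["event"].to_numpy(bool)
    tl, el = group_low["time"].to_numpy(float), group_low["event"].to_numpy(bool)
    all_t = np.concatenate([th, tl])
    all_e = np.concatenate([eh, el])
    if not all_e.any():
        raise ValueError("log-rank test undefined with no observed events")
    o_minus_e = 0.0
    var = 0.0
    for time in np.unique(all_t[all_e]):
        n_high = np.sum(th >= time)
        n_low = np.sum(tl >= time)
        n = n_high + n_low
        d = np.sum((all_t == time) & all_e)
        d_high = np.sum((th == time) & eh)
        o_minus_e += d_high - d * n_high / n
        if n > 1:
            var += d * (n - d) * n_high * n_low / (n**2 * (n - 1))
    chi_square = 0.0 if var == 0 else float(o_minus_e**2 / var)
    p_value = float(stats.chi2.sf(chi_square, df=1)) if var > 0 else 1.0
    return chi_square, p_value, float(o_minus_e)


def survival_screen(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: list[str] | None = None,
    min_cohort_size: int = MIN_COHORT_SIZE,
) -> pd.DataFrame:
    """Median-split log-rank screen over every (gene, cohort) pair.

    ``expression`` is genes x patients; ``clinical`` needs patient_id,
    cancer_type, os_time and os_event columns.  Cohorts with fewer than
    ``min_cohort_size`` patients are skipped with a warning, as are
    degenerate genes (constant expression within a cohort).  Patients with
    time 0 and no event are uninformative and dropped.

    Returns a DataFrame with columns gene_id, cohort, p_value, fdr,
    direction, n_high, n_low.
    """
    clinical = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    genes = list(expression.index) if genes is None else [g for g in genes if g in expression.index]
    rows = []
    for cohort, sub in clinical.groupby("cancer_type", sort=True):
        uninformative = (sub["os_time"] == 0) & (sub["os_event"] == 0)
        if uninformative.any():
            warnings.warn(f"{cohort}: dropping {int(uninformative.sum())} records with time 0 and no event")
            sub = sub[~uninformative]
        patients = [p for p in sub.index if p in expression.columns]
        if len(patients) < min_cohort_size:
            warnings.warn(f"cohort {cohort} skipped: {len(patients)} patients < {min_cohort_size}")
            continue
        records = pd.DataFrame(
            {"time": sub.loc[patients, "os_time"].astype(float),
             "event": sub.loc[patients, "os_event"].astype(bool)},
            index=patients,
        )
        for gene in genes:
            expr = expression.loc[gene, patients]
            try:
                labels = median_split(expr)
            except ValueError:
                warnings.warn(f"gene {gene} degenerate in cohort {cohort}; skipped")
                continue
            high = records.loc[labels[labels == "high"].index]
            low = records.loc[labels[labels == "low"].index]
            try:
                chi2, p, ome = logrank_test(high, low)
            except ValueError:
                warnings.warn(f"gene {gene} in cohort {cohort}: no events; skipped")
                continue
            rows.append(
                {
                    "gene_id": gene,
                    "cohort": cohort,
                    "chi_square": chi2,
                    "p_value": p,
                    "o_minus_e_high": ome,
                    "direction": POOR if ome > 0 else BETTER,
                    "n_high": len(high),
                    "n_low": len(low),
                }
            )
    screen = pd.DataFrame(
        rows,
        columns=["gene_id", "cohort", "chi_square", "p_value", "o_minus_e_high",
                 "direction", "n_high", "n_low"],
    )
    if len(screen):
        # optional extension; significance in rollups uses the raw p-values
        screen["fdr"] = np.nan
        for cohort, idx in screen.groupby("cohort").groups.items():
            screen.loc[idx, "fdr"] = benjamini_hochberg(screen.loc[idx, "p_value"].to_numpy())
    else:
        screen["fdr"] = pd.Series(dtype=float)
    return screen


@dataclass(frozen=True)
class MultiCohortRollup:
    """Genes significant in several cohorts, with direction consistency."""

    table: pd.DataFrame  # gene_id, overlap_count, directions, consistency
    contradictory: frozenset

    def consistent_genes(self) -> frozenset:
        t = self.table
        return frozenset(t.loc[t["consistency"] == "consistent", "gene_id"])

    def direction_of(self, gene: str) -> str:
        row = self.table[self.table["gene_id"] == gene]
        if row.empty or row["consistency"].iloc[0] != "consistent":
            raise KeyError(f"{gene} has no consistent direction")
        return row["directions"].iloc[0][0]


def rollup_cohorts(
    summaries: pd.DataFrame, min_cohorts: int = 2, alpha: float = ALPHA
) -> MultiCohortRollup:
    """Collect genes significant (raw p < alpha) in >= min_cohorts cohorts.

    Genes significant with both prognosis directions across cohorts are
    labelled contradictory; they are tabulated but excluded from consensus
    input downstream.
    """
    if len(summaries) == 0:
        return MultiCohortRollup(
            table=pd.DataFrame(columns=["gene_id", "overlap_count", "directions", "consistency"]),
            contradictory=frozenset(),
        )
    sig = summaries[summaries["p_value"] < alpha]
    rows = []
    for gene, sub in sig.groupby("gene_id", sort=True):
        if len(sub) < min_cohorts:
            continue
        directions = tuple(sorted(sub["direction"].unique()))
        consistency = "consistent" if len(directions) == 1 else "contradictory"
        rows.append(
            {
                "gene_id": gene,
                "overlap_count": len(sub),
                "directions": directions,
                "consistency": consistency,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "overlap_count", "directions", "consistency"])
    contradictory = frozenset(table.loc[table["consistency"] == "contradictory", "gene_id"])
    return MultiCohortRollup(table=table, contradictory=contradictory)
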