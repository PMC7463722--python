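"""Consensus integration and clinical association tests.

The final step of the analysis intersects, separately for up- and
downregulated genes, (i) the differential-expression calls, (ii) genes
significantly associated with overall survival in at least
``min_cohorts`` cancer types with a consistent prognosis direction, and
(iii) genes recurrently found in significant RRHO overlap windows.  Each
consensus arm is further split by prognosis direction, yielding four
disjoint gene lists.  Clinical characteristics of the high-similarity
patient group are tested with a Welch t-test (age) and per-category
two-sided Fisher exact tests (T/N/M stage).

``run_pipeline`` chains every stage — simulation or file input,
differential expression, per-patient RRHO, occurrence filtering, the
survival screen, rollup, consensus and clinical tests — into one
deterministic JSON-serializable report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from acidadapt import de as de_mod
from acidadapt import io as io_mod
from acidadapt import rrho as rrho_mod
from acidadapt import simulate as sim_mod
from acidadapt import survival as surv_mod
from acidadapt.survival import BETTER, POOR

STAGE_VOCABULARY = sim_mod.STAGE_LABELS


@dataclass(frozen=True)
class ConsensusGeneLists:
    """Four disjoint consensus sets plus Venn bookkeeping per arm."""

    up_poor: frozenset
    up_better: frozenset
    down_poor: frozenset
    down_better: frozenset
    venn: dict  # arm -> region sizes for (DE, OS, RRHO)

    def as_dict(self) -> dict[str, frozenset]:
        return {
            "up_poor": self.up_poor,
            "up_better": self.up_better,
            "down_poor": self.down_poor,
            "down_better": self.down_better,
        }


def _venn_regions(a: set, b: set, c: set) -> dict[str, int]:
    return {
        "de": len(a),
        "os": len(b),
        "rrho": len(c),
        "de_os": len(a & b),
        "de_rrho": len(a & c),
        "os_rrho": len(b & c),
        "de_os_rrho": len(a & b & c),
    }


def venn_consensus(
    de_result: pd.DataFrame,
    rollup: surv_mod.MultiCohortRollup,
    rrho_genes: set,
) -> ConsensusGeneLists:
    """Intersect DE calls, consistent multi-cohort OS genes and RRHO genes.

    Genes whose survival direction contradicts itself across cohorts are
    excluded entirely.  Raises if the gene namespaces do not overlap at
    all (a symptom of mismatched identifier schemes).
    """
    universe = set(de_result.index)
    rrho_genes = set(rrho_genes)
    rollup_genes = set(rollup.table["gene_id"]) if len(rollup.table) else set()
    for name, other in (("rrho", rrho_genes), ("survival rollup", rollup_genes)):
        if other and not (other & universe):
            raise ValueError(f"gene namespace mismatch: no {name} gene appears in the DE result")

    os_consistent = rollup.consistent_genes()
    direction = {
        row.gene_id: row.directions[0]
        for row in rollup.table.itertuples()
        if row.consistency == "consistent"
    }
    de_up = set(de_result.index[de_result["call"] == "up"])
    de_down = set(de_result.index[de_result["call"] == "down"])

    sets = {}
    venn = {}
    for arm, de_set in (("up", de_up), ("down", de_down)):
        consensus = de_set & os_consistent & rrho_genes
        sets[f"{arm}_poor"] = frozenset(g for g in consensus if direction[g] == POOR)
        sets[f"{arm}_better"] = frozenset(g for g in consensus if direction[g] == BETTER)
        venn[arm] = _venn_regions(de_set, os_consistent, rrho_genes)
    return ConsensusGeneLists(venn=venn, **sets)


def age_association(
    clinical: pd.DataFrame, pooled: bool = False
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided t-test of age between high-similarity and remaining patients.

    Welch's unequal-variance form by default; ``pooled=True`` gives the
    Student form.  Returns (t, p, (mean_high, mean_rest)).
    """
    if "is_high_similarity" not in clinical.columns:
        raise ValueError("clinical table needs an is_high_similarity column")
    ages = clinical["age"].astype(float)
    mask = clinical["is_high_similarity"].astype(bool)
    high = ages[mask].dropna()
    rest = ages[~mask].dropna()
    if len(high) < 2 or len(rest) < 2:
        raise ValueError("each group needs at least 2 patients with recorded age")
    t, p = stats.ttest_ind(high, rest, equal_var=pooled)
    return float(t), float(p), (float(high.mean()), float(rest.mean()))


def stage_association(clinical: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Per-category Fisher exact tests of stage membership vs similarity group.

    For each stage category c on the axis, the 2x2 table crosses
    (stage == c) with (high similarity); the two-sided p-value sums the
    probabilities of tables no more probable than the observed one (the
    conventional probability-mass definition).  The sample odds ratio
    ad/bc is reported, with a Haldane 0.5 correction (flagged) only when
    a zero cell occurs.
    """
    if axis not in STAGE_VOCABULARY:
        raise ValueError(f"axis must be one of {sorted(STAGE_VOCABULARY)}")
    col = f"stage_{axis}"
    valid = STAGE_VOCABULARY[axis]
    sub = clinical[clinical[col].isin(valid)]
    mask = sub["is_high_similarity"].astype(bool)
    rows = []
    for category in valid:
        in_cat = sub[col] == category
        a = int((mask & in_cat).sum())       # high similarity, this stage
        b = int((mask & ~in_cat).sum())      # high similarity, other stage
        c = int((~mask & in_cat).sum())
        d = int((~mask & ~in_cat).sum())
        if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
            warnings.warn(f"stage {category}: empty margin; skipped")
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        haldane = min(a, b, c, d) == 0
        if haldane:
            orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            orr = a * d / (b * c)
        rows.append(
            {
                "category": category,
                "odds_ratio": float(orr),
                "p_value": float(p),
                "n_high_in": a,
                "n_high_out": b,
                "n_rest_in": c,
                "n_rest_out": d,
                "haldane_corrected": haldane,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["category", "odds_ratio", "p_value", "n_high_in", "n_high_out",
                 "n_rest_in", "n_rest_out", "haldane_corrected"],
    )


DEFAULT_THRESHOLDS = {
    "min_cpm": 1.0,
    "min_samples": 3,
    "lfc": 0.5,
    "fdr": 0.05,
    "rrho_alpha": 0.05,
    "high_threshold": 0.20,
    "min_occurrence": None,  # absolute count; overrides min_occurrence_frac
    "min_occurrence_frac": 0.4,  # fraction of high-similarity comparisons
    "min_cohorts": 2,
    "survival_alpha": 0.05,
}


def _cellline_config(block: dict, seed: int) -> sim_mod.CellLineSimConfig:
    block = dict(block)
    eff = block.pop("effect_size_distribution", None)
    cfg = sim_mod.CellLineSimConfig(seed=seed, **block)
    if eff is not None:
        cfg = replace(cfg, effect_size_distribution=sim_mod.EffectSizeDistribution(**eff))
    return cfg


def _hazard_genes_from_truth(truth: sim_mod.CellLineTruth, spec: dict) -> dict[str, float]:
    """Pick the strongest planted genes as hazard genes, beta following the sign."""
    n = int(spec.get("n_genes", 8))
    beta = float(spec.get("beta", 1.0))
    planted = truth.planted_log2fc
    chosen = planted.abs().sort_values(ascending=False, kind="stable").index[:n]
    return {g: beta * float(np.sign(planted[g])) for g in sorted(chosen)}


def run_pipeline(config: dict, seed: int | None = None) -> dict:
    """Execute the full analysis and return a JSON-serializable report.

    ``config`` has three sections:

    inputs
        Either ``simulate: {cell_lines: {...}, cohort: {...}}`` or
        ``paths: {counts, design, tumor, control, clinical}``.
    thresholds
        Overrides of :data:`DEFAULT_THRESHOLDS`.
    seed
        Global seed (the ``seed`` argument takes precedence).

    The report is fully determined by config + seed.
    """
    seed = int(config.get("seed", 0) if seed is None else seed)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    inputs = config.get("inputs", {})
    report: dict = {"seed": seed}

    truth_block = None
    if "simulate" in inputs:
        sim_block = inputs["simulate"]
        cl_cfg = _cellline_config(sim_block.get("cell_lines", {}), seed)
        counts, design, cl_truth = sim_mod.simulate_cellline_counts(cl_cfg)
        truth_block = {"n_responsive": int((cl_truth.planted_log2fc != 0).sum())}
    elif "paths" in inputs:
        paths = inputs["paths"]
        counts = io_mod.read_counts(paths["counts"])
        design = io_mod.read_design(paths["design"])
        cl_truth = None
    else:
        raise ValueError("config.inputs must contain 'simulate' or 'paths'")

    # --- differential expression -----------------------------------------
    try:
        de_result = de_mod.run_de(
            counts, design,
            min_cpm=thresholds["min_cpm"], min_samples=thresholds["min_samples"],
            lfc_threshold=thresholds["lfc"], fdr_threshold=thresholds["fdr"],
        )
    except ValueError as err:
        raise RuntimeError(f"pipeline stage 'differential expression' failed: {err}") from err
    report["de"] = {
        "n_genes_input": int(counts.shape[0]),
        "n_expressed": int(len(de_result)),
        "n_up": int((de_result["call"] == "up").sum()),
        "n_down": int((de_result["call"] == "down").sum()),
    }
    signature = rrho_mod.make_ranked_list(de_result["log2fc"])

    # --- patient cohort ---------------------------------------------------
    if "simulate" in inputs:
        co_block = dict(inputs["simulate"].get("cohort", {}))
        target_rho = co_block.pop("target_rank_correlation", None)
        hazard_spec = co_block.pop("hazard_from_truth", None)
        co_cfg = sim_mod.PatientSimConfig(seed=seed, **co_block)
        if target_rho is not None:
            co_cfg = replace(
                co_cfg,
                signature_scale=sim_mod.scale_for_rank_correlation(
                    signature, co_cfg.tumor_noise_sd, target_rho
                ),
            )
        if hazard_spec is not None and cl_truth is not None:
            hazard = _hazard_genes_from_truth(cl_truth, hazard_spec)
            hazard = {g: b for g, b in hazard.items() if g in set(signature.gene_ids)}
            co_cfg = replace(co_cfg, hazard_genes=hazard)
        tumor, control, clinical, acid_truth = sim_mod.simulate_patient_cohort(co_cfg, signature)
        truth_block["n_acid_like"] = int(acid_truth.sum())
    else:
        tumor = io_mod.read_expression(paths["tumor"])
        control = io_mod.read_expression(paths["control"])
        clinical = io_mod.read_clinical(paths["clinical"])
        acid_truth = None

    # --- per-patient RRHO -------------------------------------------------
    patients = list(tumor.columns)
    log2fc = tumor - control
    similarities: dict[str, float] = {}
    high_flags: dict[str, bool] = {}
    overlap_sets = {}
    for patient in patients:
        patient_list = rrho_mod.make_ranked_list(log2fc[patient])
        sig_h, pat_h = rrho_mod.harmonize_universe(signature, patient_list)
        result = rrho_mod.rrho_matrix(sig_h, pat_h)
        sim, high = rrho_mod.similarity_score(
            result, alpha=thresholds["rrho_alpha"], high_threshold=thresholds["high_threshold"]
        )
        similarities[patient] = sim
        high_flags[patient] = high
        if high:
            overlap_sets[patient] = rrho_mod.extract_overlap_genes(
                result, sig_h, pat_h, alpha=thresholds["rrho_alpha"]
            )

    n_high = sum(high_flags.values())
    if overlap_sets:
        table = rrho_mod.occurrence_counts(list(overlap_sets.values()))
        min_occ = thresholds["min_occurrence"]
        if min_occ is None:
            min_occ = max(1, int(np.ceil(thresholds["min_occurrence_frac"] * len(overlap_sets))))
        rrho_genes = rrho_mod.threshold_filter(table, min_occurrence=min_occ)
    else:
        min_occ = 0
        rrho_genes = frozenset()
    report["rrho"] = {
        "n_patients": len(patients),
        "n_high_similarity": int(n_high),
        "high_similarity_fraction": float(n_high / len(patients)),
        "min_occurrence": int(min_occ),
        "n_recurrent_overlap_genes": len(rrho_genes),
    }

    # --- survival screen --------------------------------------------------
    de_called = de_result.index[de_result["call"] != "ns"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen = surv_mod.survival_screen(tumor, clinical, genes=de_called)
    rollup = surv_mod.rollup_cohorts(
        screen, min_cohorts=thresholds["min_cohorts"], alpha=thresholds["survival_alpha"]
    )
    per_cohort = (
        screen[screen["p_value"] < thresholds["survival_alpha"]]
        .groupby("cohort")["gene_id"].count().to_dict()
        if len(screen) else {}
    )
    report["survival"] = {
        "n_genes_screened": len(de_called),
        "per_cohort_significant": {str(k): int(v) for k, v in per_cohort.items()},
        "n_rollup_genes": int(len(rollup.table)),
        "n_contradictory": len(rollup.contradictory),
    }

    # --- consensus and clinical associations ------------------------------
    consensus = venn_consensus(de_result, rollup, rrho_genes)
    report["consensus"] = {
        "sets": {k: sorted(v) for k, v in consensus.as_dict().items()},
        "sizes": {k: len(v) for k, v in consensus.as_dict().items()},
        "venn": consensus.venn,
    }

    clin = clinical.copy()
    clin["is_high_similarity"] = clin["patient_id"].map(high_flags).fillna(False).astype(bool)
    clinical_report: dict = {}
    try:
        t, p, (m_high, m_rest) = age_association(clin)
        clinical_report["age"] = {
            "t_statistic": t, "p_value": p, "mean_high": m_high, "mean_rest": m_rest,
        }
    except ValueError as err:
        clinical_report["age"] = {"skipped": str(err)}
    for axis in ("T", "N", "M"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = stage_association(clin, axis)
        clinical_report[f"stage_{axis}"] = [
            {k: row[k] for k in ("category", "odds_ratio", "p_value", "haldane_corrected")}
            for _, row in table.iterrows()
        ]
    report["clinical"] = clinical_report
    if truth_block is not None:
        report["truth"] = truth_block
    return report
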