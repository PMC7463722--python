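"""Synthetic data generators with known ground truth.

Two generators mirror the structure of the study data:

``simulate_cellline_counts``
    Gene-level RNA-seq counts for several cancer cell lines grown at acidic
    and control pH, in replicates.  A configurable subset of genes carries a
    planted pH-response log2 fold change shared across cell lines, on top of
    per-gene, per-cell-line baseline offsets and negative-binomial noise.

``simulate_patient_cohort``
    Paired tumor/normal expression for a patient cohort in which a
    configurable fraction of patients is "acid-like": their tumor-vs-normal
    log2 fold changes follow the acid-adaptation signature (scaled by
    ``signature_scale``) plus Gaussian noise, so the rank correlation with
    the signature is tunable.  Survival times follow an exponential model
    whose hazard is log-linear in standardized tumor expression of selected
    genes, with independent exponential censoring.  Age and TNM stage
    frequencies differ between acid-like and other patients.

All randomness derives from one integer seed through named sub-streams, so
adding a new generator never perturbs the draws of existing ones, and equal
seeds give bit-identical output.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from acidadapt.rrho import RankedGeneList

ACID = "acid"
CONTROL = "control"

#: Cancer-type labels used when a cohort config does not name its own.
DEFAULT_CANCER_TYPES = ("PAAD", "BRCA", "LUAD", "GBM", "COAD", "OV", "THCA", "STAD")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for sub-stream ``name`` of global ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValueError(f"invalid config field '{field_name}': {message}")


def _check_range(rng_pair, field_name: str) -> tuple[float, float]:
    lo, hi = float(rng_pair[0]), float(rng_pair[1])
    _require(math.isfinite(lo) and math.isfinite(hi), field_name, "must be finite")
    _require(lo <= hi, field_name, f"lower bound {lo} exceeds upper bound {hi}")
    return lo, hi


@dataclass(frozen=True)
class EffectSizeDistribution:
    """Planted log2FC magnitudes: |Normal(location, scale)| with random sign.

    ``prob_up`` is the probability of an upregulated (positive) effect; the
    default reflects the roughly 2:1 up/down split of the acid response.
    """

    location: float = 2.0
    scale: float = 0.5
    prob_up: float = 0.65

    def validate(self) -> None:
        _require(math.isfinite(self.location), "effect_size_distribution.location", "must be finite")
        _require(
            math.isfinite(self.scale) and self.scale >= 0,
            "effect_size_distribution.scale",
            "must be finite and >= 0",
        )
        _require(0.0 <= self.prob_up <= 1.0, "effect_size_distribution.prob_up", "must be in [0, 1]")


@dataclass(frozen=True)
class CellLineSimConfig:
    """Configuration of the cell-line count generator.

    The default design mirrors the experiment the pipeline targets: three
    cell lines, two pH conditions, three replicates (18 libraries).
    ``dispersion`` is the negative-binomial dispersion phi in the
    variance function mu + phi * mu**2; 0 degenerates to Poisson.
    """

    n_genes: int = 5000
    n_cell_lines: int = 3
    n_replicates: int = 3
    frac_responsive: float = 0.05
    effect_size_distribution: EffectSizeDistribution = field(default_factory=EffectSizeDistribution)
    baseline_log_mean_range: tuple[float, float] = (3.0, 12.0)
    cellline_effect_sd: float = 0.5
    dispersion: float = 0.05
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_genes >= 1, "n_genes", "must be a positive integer")
        _require(self.n_cell_lines >= 1, "n_cell_lines", "must be a positive integer")
        _require(self.n_replicates >= 1, "n_replicates", "must be a positive integer")
        _require(0.0 <= self.frac_responsive <= 1.0, "frac_responsive", "must be in [0, 1]")
        self.effect_size_distribution.validate()
        _check_range(self.baseline_log_mean_range, "baseline_log_mean_range")
        _require(
            math.isfinite(self.cellline_effect_sd) and self.cellline_effect_sd >= 0,
            "cellline_effect_sd",
            "must be finite and >= 0",
        )
        _require(
            math.isfinite(self.dispersion) and self.dispersion >= 0,
            "dispersion",
            "must be finite and >= 0",
        )
        lo, _ = _check_range(self.library_size_range, "library_size_range")
        _require(lo > 0, "library_size_range", "library sizes must be positive")


@dataclass(frozen=True)
class CellLineTruth:
    """Ground truth of one cell-line simulation."""

    planted_log2fc: pd.Series
    responsive_up: frozenset
    responsive_down: frozenset


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2) counts; phi = 0 gives Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_cellline_counts(
    config: CellLineSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CellLineTruth]:
    """Draw a gene x sample count matrix with a planted shared pH response.

    Within each cell line the expected count of a responsive gene at acidic
    pH is ``2**planted_log2fc`` times its expected count in the control
    condition (before sampling noise); non-responsive genes have identical
    expectations across conditions.

    Returns
    -------
    counts : DataFrame, genes x samples, non-negative integers.
    design : DataFrame with columns sample_id, cell_line, ph, replicate.
    truth : CellLineTruth
    """
    config.validate()
    rng = substream(config.seed, "cell-lines")

    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    n_responsive = int(round(config.frac_responsive * config.n_genes))
    responsive_idx = rng.choice(config.n_genes, size=n_responsive, replace=False)

    eff = config.effect_size_distribution
    magnitudes = np.abs(rng.normal(eff.location, eff.scale, size=n_responsive))
    signs = np.where(rng.random(n_responsive) < eff.prob_up, 1.0, -1.0)
    planted = np.zeros(config.n_genes)
    planted[responsive_idx] = signs * magnitudes

    lo, hi = config.baseline_log_mean_range
    baseline_log2 = rng.uniform(lo, hi, size=config.n_genes)

    lines = [f"CL{i + 1}" for i in range(config.n_cell_lines)]
    columns, rows, counts_cols = [], [], []
    for line in lines:
        offsets = rng.normal(0.0, config.cellline_effect_sd, size=config.n_genes)
        base = np.exp2(baseline_log2 + offsets)
        norm = base.sum()  # control-composition total defines the depth unit
        for ph in (CONTROL, ACID):
            cond_mean = base * np.exp2(planted) if ph == ACID else base
            for rep in range(1, config.n_replicates + 1):
                lib = rng.uniform(*config.library_size_range)
                mu = lib * cond_mean / norm
                counts_cols.append(_nb_draws(rng, mu, config.dispersion))
                sample_id = f"{line}_{ph}_r{rep}"
                columns.append(sample_id)
                rows.append({"sample_id": sample_id, "cell_line": line, "ph": ph, "replicate": rep})

    counts = pd.DataFrame(
        np.column_stack(counts_cols).astype(np.int64), index=genes, columns=columns
    )
    counts.index.name = "gene_id"
    design = pd.DataFrame(rows)

    planted_series = pd.Series(planted, index=genes, name="planted_log2fc")
    truth = CellLineTruth(
        planted_log2fc=planted_series,
        responsive_up=frozenset(genes[planted > 0]),
        responsive_down=frozenset(genes[planted < 0]),
    )
    return counts, design, truth


def _default_stage_probs() -> dict:
    # Acid-like tumors skew toward larger primary tumors (T3 over T2),
    # echoing the clinical association the pipeline is meant to detect.
    return {
        "T": {"acid_like": [0.10, 0.25, 0.55, 0.10], "other": [0.15, 0.45, 0.30, 0.10]},
        "N": {"acid_like": [0.50, 0.30, 0.15, 0.05], "other": [0.50, 0.30, 0.15, 0.05]},
        "M": {"acid_like": [0.90, 0.10], "other": [0.90, 0.10]},
    }


@dataclass(frozen=True)
class PatientSimConfig:
    """Configuration of the paired tumor/normal patient-cohort generator."""

    n_patients: int = 100
    frac_acid_like: float = 0.2
    signature_scale: float = 1.0
    tumor_noise_sd: float = 1.0
    hazard_genes: dict = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 1000.0  # per day; median OS ~ 2 years
    censoring_rate: float = 0.0
    age_means: tuple[float, float] = (59.0, 62.2)  # (acid-like, other)
    age_sd: float = 10.0
    stage_probs: dict = field(default_factory=_default_stage_probs)
    cancer_types: tuple[str, ...] = DEFAULT_CANCER_TYPES
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_patients >= 1, "n_patients", "must be a positive integer")
        _require(0.0 <= self.frac_acid_like <= 1.0, "frac_acid_like", "must be in [0, 1]")
        _require(math.isfinite(self.signature_scale), "signature_scale", "must be finite")
        _require(
            math.isfinite(self.tumor_noise_sd) and self.tumor_noise_sd >= 0,
            "tumor_noise_sd",
            "must be finite and >= 0",
        )
        _require(
            math.isfinite(self.baseline_hazard) and self.baseline_hazard > 0,
            "baseline_hazard",
            "must be > 0",
        )
        _require(
            math.isfinite(self.censoring_rate) and self.censoring_rate >= 0,
            "censoring_rate",
            "must be >= 0",
        )
        _require(self.age_sd > 0, "age_sd", "must be > 0")
        for axis, groups in self.stage_probs.items():
            for group, probs in groups.items():
                total = float(np.sum(probs))
                _require(
                    abs(total - 1.0) <= 1e-9,
                    f"stage_probs[{axis}][{group}]",
                    f"probabilities sum to {total}, not 1",
                )
        _require(len(self.cancer_types) >= 1, "cancer_types", "must be non-empty")


STAGE_LABELS = {"T": ["T1", "T2", "T3", "T4"], "N": ["N0", "N1", "N2", "N3"], "M": ["M0", "M1"]}


def simulate_patient_cohort(
    config: PatientSimConfig, signature: RankedGeneList
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw a paired tumor/normal cohort tied to an acid-adaptation signature.

    For acid-like patients the per-gene tumor-vs-normal log2FC is
    ``signature_scale * signature score + Normal(0, tumor_noise_sd)``; for
    the remaining patients it is pure noise.  Expression tables are on the
    log2 scale (tumor = control + log2FC).

    Returns
    -------
    tumor, control : DataFrames, genes x patients (log2 expression).
    clinical : DataFrame with columns patient_id, cancer_type, age,
        stage_T, stage_N, stage_M, os_time, os_event.
    truth : boolean Series, True for acid-like patients.
    """
    config.validate()
    genes = np.asarray(signature.gene_ids)
    missing = [g for g in config.hazard_genes if g not in set(genes)]
    if missing:
        raise ValueError(f"hazard_genes absent from the signature universe: {missing}")

    score = pd.Series(signature.scores, index=genes).sort_index()
    genes_sorted = score.index.to_numpy()
    n_genes, n = len(genes_sorted), config.n_patients
    patients = np.array([f"P{i:04d}" for i in range(n)])

    rng = substream(config.seed, "cohort")
    n_acid = int(round(config.frac_acid_like * n))
    acid_mask = np.zeros(n, dtype=bool)
    acid_mask[rng.choice(n, size=n_acid, replace=False)] = True

    base = rng.normal(8.0, 2.0, size=n_genes)
    control = base[:, None] + rng.normal(0.0, 0.5, size=(n_genes, n))
    noise = rng.normal(0.0, config.tumor_noise_sd, size=(n_genes, n)) if config.tumor_noise_sd > 0 else 0.0
    log2fc = config.signature_scale * score.to_numpy()[:, None] * acid_mask[None, :] + noise
    tumor = control + log2fc

    tumor_df = pd.DataFrame(tumor, index=genes_sorted, columns=patients)
    control_df = pd.DataFrame(control, index=genes_sorted, columns=patients)
    tumor_df.index.name = control_df.index.name = "gene_id"

    # survival: exponential event times with log-linear hazard
    rng_surv = substream(config.seed, "survival")
    log_hr = np.zeros(n)
    for gene, beta in sorted(config.hazard_genes.items()):
        expr = tumor_df.loc[gene].to_numpy()
        sd = expr.std()
        z = (expr - expr.mean()) / sd if sd > 0 else np.zeros(n)
        log_hr += float(beta) * z
    hazard = config.baseline_hazard * np.exp(log_hr)
    event_time = rng_surv.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng_surv.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = event_time <= censor_time

    rng_clin = substream(config.seed, "clinical")
    mean_acid, mean_other = config.age_means
    age = np.where(
        acid_mask,
        rng_clin.normal(mean_acid, config.age_sd, size=n),
        rng_clin.normal(mean_other, config.age_sd, size=n),
    )
    age = np.clip(age, 18.0, None)
    stages = {}
    for axis, labels in STAGE_LABELS.items():
        probs = config.stage_probs[axis]
        draw = np.empty(n, dtype=object)
        for group, mask in (("acid_like", acid_mask), ("other", ~acid_mask)):
            k = int(mask.sum())
            if k:
                draw[mask] = rng_clin.choice(labels, size=k, p=np.asarray(probs[group], dtype=float))
        stages[axis] = draw
    cancer_type = rng_clin.choice(np.asarray(config.cancer_types, dtype=object), size=n)

    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "cancer_type": cancer_type,
            "age": age,
            "stage_T": stages["T"],
            "stage_N": stages["N"],
            "stage_M": stages["M"],
            "os_time": os_time,
            "os_event": os_event.astype(int),
        }
    )
    truth = pd.Series(acid_mask, index=patients, name="acid_like")
    return tumor_df, control_df, clinical, truth


def scale_for_rank_correlation(
    signature: RankedGeneList,
    tumor_noise_sd: float,
    target_spearman: float,
    n_replicates: int = 20,
    seed: int = 714025,
) -> float:
    """Signature scale giving the requested mean Spearman correlation.

    The expected rank correlation between ``scale * score + noise`` and the
    score vector depends on the score distribution's shape (log2FC vectors
    are heavy-tailed), so the scale is found by bisection on a seeded
    Monte-Carlo estimate of the mean Spearman correlation over
    ``n_replicates`` noise draws.  The internal seed is fixed so the
    mapping from target to scale is deterministic.
    """
    if not 0 < target_spearman < 1:
        raise ValueError("target_spearman must be in (0, 1)")
    scores = np.asarray(signature.scores, dtype=float)
    if np.std(scores) == 0:
        raise ValueError("signature scores are constant; correlation target unreachable")
    if tumor_noise_sd == 0:
        return 1.0  # noise-free: any positive scale gives correlation 1
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, tumor_noise_sd, size=(n_replicates, scores.size))
    score_ranks = stats.rankdata(scores)

    def mean_spearman(scale: float) -> float:
        perturbed = scale * scores[None, :] + noise
        rhos = [
            np.corrcoef(stats.rankdata(row), score_ranks)[0, 1] for row in perturbed
        ]
        return float(np.mean(rhos))

    lo, hi = 1e-6, 1.0
    while mean_spearman(hi) < target_spearman:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("failed to bracket the target rank correlation")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mean_spearman(mid) < target_spearman:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
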