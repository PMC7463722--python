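# Methods

This note documents the statistical models behind `acidadapt`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that affect results.

## Differential expression of the shared pH response

**Model.** Gene-level counts from `L` cell lines × 2 pH conditions ×
replicates are filtered (CPM ≥ 1 in ≥ 3 samples, the smallest group
size), TMM-normalized, and transformed to
`log2((count + 0.5) / (effective library size + 1) * 1e6)`. Each gene is
fit by weighted least squares against
`~ 1 + cell_line + pH`, so the pH coefficient estimates the acid
response *shared* across lines while cell-line terms absorb baseline
differences. With exactly three lines, fixed blocking factors are a
fully specified and statistically defensible alternative to a
random-effect consensus correlation; this is a deliberate design choice
of the package.

**TMM.** The reference sample is the one whose 75th-percentile CPM is
closest to the mean of those percentiles (deterministic and robust). For
each sample, per-gene M (log2 ratio of library-normalized proportions)
and A (average log2 abundance) values are computed over genes positive
in both sample and reference; 30% of M and 5% of A are trimmed from each
tail (rank-based, average ranks for ties), and the factor is 2 to the
inverse-asymptotic-variance weighted mean of the surviving M values,
rescaled so factors have geometric mean 1. Factors below `2^1e-6` in
magnitude snap to exactly 1 to avoid spurious micro-adjustments.

**Precision weights.** Per gene, the unweighted fit's
sqrt(residual sd) is smoothed against average log-CPM by LOWESS
(span 0.5, 3 robustness iterations, delta = 1% of the abundance range
for speed); the weight of each observation is the inverse fourth power
of the trend at its fitted log-CPM, clamped to the trend endpoints
outside its range. The trend floor is 1e-6 so weights stay finite.

**Moderated statistics.** Residual variances `s_g²` (df `d = n − p`) are
shrunk toward a prior: moments of `log s_g²` are matched to a log
scaled-F distribution, giving prior df `d0` (via a Newton trigamma
inverse) and prior variance `s0²`; the posterior is
`(d0·s0² + d·s_g²)/(d0 + d)`. If the variance equation has no positive
solution, `d0 = ∞` and every posterior variance equals `s0²` (a normal
reference is then used instead of a t). The moderated t refers to
`t(d + d0)`; BH adjustment is applied across retained genes and calls
require FDR < 0.05 *and* |log2FC| > 0.5 (both thresholds configurable).

## RRHO and the similarity score

Both lists are ranked descending by log2FC, ties broken by gene id so
rankings are total and deterministic; rank 1 is the most upregulated
gene in both lists, so the low-rank corner of the map captures
co-upregulation. The default grid uses step `s = floor(N/10)`, tiling
the rank space into a 10 × 10 matrix of 100 windows; each window (i, j)
holds the exact overlap count `k` of the two top segments and the
hypergeometric over-enrichment tail `P(X ≥ k)`, computed by summing log
pmf terms (log-gamma + logsumexp) for stability at extreme p-values.
Window p-values are used raw — no multiplicity correction — matching the
similarity score's definition as the fraction of windows with p < 0.05.
A comparison is "high similarity" when that fraction strictly exceeds
0.20.

The signed display map stores `−log10 p_over` for windows at or above
the expected overlap `ij/N`, and `log10 P(X ≤ k)` (negative) for
under-enriched windows; only over-enrichment feeds the similarity score
and the overlap-gene extraction, which unions `top-i ∩ top-j` over
significant over-enriched windows.

**Calibration caveat.** Because thresholds run up to N, the last grid
row and column compare whole lists (k is deterministic, p = 1), and the
discrete hypergeometric tail is conservative in coarse windows. The
expected null similarity on the default 10 × 10 grid is therefore ~0.03,
not exactly 0.05; it approaches 0.05 only as the grid becomes fine
relative to N. The calibration tests use a 30 × 30 grid on 1,500 genes,
where the measured null mean is ≈ 0.04. This conservativeness means the
0.20 classification threshold is, if anything, slightly harder to cross
for null patients than the nominal arithmetic suggests.

**Occurrence filter.** Overlap gene sets are collected from
high-similarity comparisons only, and a gene is kept when it recurs in
at least `min_occurrence` of them. In the pipeline this threshold
defaults to 40% of the number of high-similarity comparisons (an
absolute count can be configured instead), scaling the intent of a
fixed recurrence cut to cohorts of any size.

## Survival screen

Per gene and cohort, expression is median-split with ties assigned to
the low group (the cutoff itself is "low"); degenerate genes (one empty
group) are skipped. The Kaplan–Meier estimator is the standard product
limit; censored subjects at an event time remain in that time's risk
set. The log-rank statistic uses the hypergeometric variance
`d(n−d)·n_high·n_low / (n²(n−1))` at each distinct event time, and the
prognosis direction comes from the sign of `Σ(O−E)` in the
high-expression group — always defined when the test is, unlike
curve-crossing heuristics. Records with time 0 and no event are dropped
as uninformative; cohorts under 8 patients are skipped. Significance in
the screen uses raw p < 0.05 per (gene, cohort) — appropriate for a
screen of a few hundred pre-selected candidates — with a BH column
available as an extension. Rollups keep genes significant in at least 2
cohorts; genes significant with both prognosis directions are labeled
contradictory and excluded from consensus input (they are reported
separately).

## Gene-set enrichment

ORA intersects every set with the expressed-gene universe and applies
the same exact hypergeometric tail as RRHO, with BH across the
collection. Preranked GSEA increments the running sum at member genes by
`|score|^w / Σ_hits |score|^w` and decrements elsewhere by
`1/(N − n_hits)`; the enrichment score is the extreme deviation. The
default exponent is `w = 1` (weighted); `w = 0` gives the rank-only
statistic used in the analytic test cases. Significance uses gene-label
permutations (the appropriate scheme for a preranked list):
`perm_p` is the frequency of same-sign null scores at least as extreme,
and NES divides the observed score by the mean magnitude of same-sign
null scores; when no same-sign null exists, NES is reported as NaN
rather than guessed. If every member gene has score exactly 0 (possible
with w > 0), hit increments fall back to equal weights.

## Clinical association tests

Age is compared between high-similarity and remaining patients by a
two-sided Welch t-test (the unequal-variance form is the safer default;
a pooled Student form is available). Stage associations test, per
category on the chosen axis after filtering to the valid vocabulary
(T1–T4, N0–N3, M0–M1), the 2 × 2 table of category membership against
similarity group with a two-sided Fisher exact test (probability-mass
definition: the p-value sums the probabilities of fixed-margin tables no
more probable than the observed one). The reported odds ratio is the
unconditional sample OR `ad/bc`; a Haldane 0.5 correction is applied —
and flagged — only when a zero cell occurs.

## Synthetic data: what it emulates, what it does not

**Cell lines.** Baseline log2 expression is uniform on [3, 12] per gene,
with Normal(0, 0.5) per-gene per-line offsets; a fraction of genes
(default 5%) carries a planted log2FC drawn as |Normal(2, 0.5)| with
P(up) = 0.65, applied multiplicatively to the acid condition's mean.
Counts are negative binomial with variance `μ + φμ²` (default φ = 0.05,
a typical cell-line dispersion; φ = 0 degenerates to Poisson), with
per-sample expected depths uniform on [0.8M, 1.2M] against the control
composition of each line. The default design is 3 lines × 2 pH × 3
replicates = 18 libraries. Within a cell line, the expected acid/control
count ratio of a responsive gene is exactly `2^planted` — the mean model
the recovery tests rely on.

**Patients.** For acid-like patients (default fraction 0.2), per-gene
tumor-vs-normal log2FC is `scale · signature score + Normal(0, σ)`
(default σ = 1); other patients get pure noise. Because rank correlation
with a heavy-tailed score vector has no convenient closed form, the
scale achieving a target Spearman correlation is found by bisection on a
seeded Monte-Carlo estimate (deterministic given the target). Survival
is exponential with hazard `h0 · exp(Σ β_g z_g)` on standardized tumor
expression (default h0 = 1/1000 per day, median OS ≈ 2 years),
independently censored by an exponential clock; a censoring rate of
`(3/7)·h0` yields ~30% censoring when hazards are near baseline. Age is
Normal (means 59 / 62.2, sd 10) and TNM stages are categorical with
acid-like patients skewed toward T3 over T2.

**Not emulated:** read-level data, batch effects beyond the cell-line
factor, cohort-specific expression platforms, and the true (unknown)
noise structure of patient tumor-vs-normal fold changes — the Gaussian
noise model is a stand-in, so passing recovery tests demonstrates the
pipeline's statistical behavior under its stated assumptions, not
performance on any real cohort.

## Determinism and problem sizes

One global integer seed drives a named sub-stream per generator
(seed × CRC32 of the stream name), so adding a generator never perturbs
existing draws, and equal seeds give bit-identical outputs. Pipeline
reports are serialized with sorted keys and sorted gene lists, making
repeated runs byte-identical. The test-suite and acceptance-script
problem sizes — 5,000-gene expression simulations, 100-patient cohorts,
hundreds of null replicates — were chosen as the smallest scales at
which the calibration and recovery properties are statistically sharp;
all complete in a few minutes on one CPU.

## Known limitations

* The survival screen is marginal (no age/stage adjustment, no Cox
  model, no competing risks).
* The moderated fit assumes the precision-weighted log-CPM values are
  approximately normal; extreme low-count genes can occasionally produce
  outlying statistics, as with any workflow of this family.
* RRHO windows are dependent, so the similarity score's null
  distribution is heavy-tailed; the score is a screening statistic, not
  a calibrated p-value.
* The occurrence filter's recurrence threshold is a convention (40% of
  comparisons by default), not an inferred quantity.
* Overlap genes are extracted from top-segment windows of a single
  descending ranking, so co-*down*regulated genes can only enter through
  near-full-list windows where relative enrichment vanishes; the
  down-direction consensus is therefore much harder to populate than the
  up direction. Surveying both ends of the lists (e.g., re-running RRHO
  on reversed rankings) would symmetrize this at the cost of a second
  pass.
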