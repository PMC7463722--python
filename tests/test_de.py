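"""Differential-expression chain: filtering, TMM, log-CPM, weights, fit, BH."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from acidadapt.de import (
    benjamini_hochberg,
    build_design_matrix,
    filter_low_counts,
    fit_shared_response,
    log_cpm,
    precision_weights,
    run_de,
    tmm_factors,
)
from _oracles import bh_stepup, tmm_factor_bruteforce


def _toy_counts(rows, samples=None):
    samples = samples or [f"S{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=samples).T


class TestFilterLowCounts:
    def test_all_zero_gene_removed(self):
        counts = _toy_counts({"gA": [5, 5, 5], "gZero": [0, 0, 0]})
        out = filter_low_counts(counts, min_cpm=1.0, min_samples=1)
        assert list(out.index) == ["gA"]

    def test_zero_threshold_is_identity(self):
        counts = _toy_counts({"gA": [5, 5, 5], "gZero": [0, 0, 0]})
        out = filter_low_counts(counts, min_cpm=0.0, min_samples=1)
        pd.testing.assert_frame_equal(out, counts)

    def test_cpm_rule_on_known_library_sizes(self):
        # three libraries of 1e6: gene (2,0,0) has CPM (2,0,0) and fails
        # min_cpm=1 in >= 2 samples; gene (2,2,0) passes
        filler = [999996, 999998, 1000000]
        counts = _toy_counts({"gBig": filler, "gFail": [2, 0, 0], "gPass": [2, 2, 0]})
        out = filter_low_counts(counts, min_cpm=1.0, min_samples=2)
        assert "gFail" not in out.index
        assert "gPass" in out.index

    def test_empty_result_raises_with_advice(self):
        counts = _toy_counts({"gA": [1, 1, 1]})
        with pytest.raises(ValueError, match="relax"):
            filter_low_counts(counts, min_cpm=1e9, min_samples=1)

    def test_gene_order_preserved(self):
        counts = _toy_counts({"g3": [10, 10, 10], "g1": [20, 20, 20], "g2": [0, 0, 0]})
        out = filter_low_counts(counts, min_cpm=1.0, min_samples=3)
        assert list(out.index) == ["g3", "g1"]


class TestTmmFactors:
    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.poisson(100, size=50)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_depth_invariance(self, rng):
        col = rng.poisson(100, size=200) + 1
        counts = pd.DataFrame({"a": col, "b": col * 10})
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), 1.0, atol=1e-12)

    def test_matches_bruteforce_on_asymmetric_composition(self, rng):
        # 10% of genes 8-fold up in sample 2, rest equal
        base = rng.poisson(200, size=100) + 1
        up = base.copy()
        up[:10] *= 8
        counts = pd.DataFrame({"ref": base, "shifted": up})
        ours = tmm_factors(counts, ref_sample="ref")
        oracle = tmm_factor_bruteforce(counts.to_numpy(), ref_idx=0)
        np.testing.assert_allclose(ours.to_numpy(), oracle, rtol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(300, 6)) + 1,
                              columns=[f"S{i}" for i in range(6)])
        factors = tmm_factors(counts)
        assert np.prod(factors) ** (1 / 6) == pytest.approx(1.0)

    def test_disjoint_support_raises(self):
        counts = pd.DataFrame({"a": [5, 0, 3, 0], "b": [0, 4, 0, 2]})
        with pytest.raises(ValueError, match="reference"):
            tmm_factors(counts, ref_sample="a")


class TestLogCpm:
    def test_zero_count_value(self):
        counts = pd.DataFrame({"s": [0] + [1] * 999999})
        lcpm = log_cpm(counts, pd.Series({"s": 1.0}))
        # (0 + 0.5)/(1e6 - 1 + 1) * 1e6 ... library here is 999999
        expected = np.log2(0.5 / (999999 + 1) * 1e6)
        assert lcpm.iloc[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_always_finite(self, rng):
        counts = pd.DataFrame(rng.poisson(1, size=(100, 4)))
        assert np.isfinite(log_cpm(counts).to_numpy()).all()

    def test_doubling_library_shifts_by_one(self, rng):
        col = rng.poisson(500, size=1000) + 100
        counts = pd.DataFrame({"a": col, "b": col * 2})
        factors = pd.Series({"a": 1.0, "b": 1.0})
        lcpm = log_cpm(counts, factors)
        diff = (lcpm["a"] - lcpm["b"]).abs()
        assert diff.max() < 0.01  # log-CPM is depth-normalized


class TestPrecisionWeights:
    def test_flat_trend_on_homoskedastic_data(self, small_design, rng):
        X = build_design_matrix(small_design)
        n_genes = 5000
        mean = rng.uniform(2, 12, size=n_genes)
        y = mean[:, None] + rng.normal(0, 0.3, size=(n_genes, len(X)))
        lcpm = pd.DataFrame(y, index=[f"G{i:05d}" for i in range(n_genes)],
                            columns=X.index)
        w = precision_weights(lcpm, small_design)
        trend_level = 1.0 / w.to_numpy() ** 0.25
        assert trend_level.max() / trend_level.min() < 1.25

    def test_weights_positive_and_finite(self, planted_simulation, small_design):
        counts, design, _ = planted_simulation
        lcpm = log_cpm(counts, tmm_factors(counts))
        w = precision_weights(lcpm, design)
        assert (w.to_numpy() > 0).all()
        assert np.isfinite(w.to_numpy()).all()

    def test_planted_decreasing_variance_gives_increasing_weights(self, small_design, rng):
        X = build_design_matrix(small_design)
        n_genes = 3000
        mean = np.sort(rng.uniform(2, 12, size=n_genes))
        sd = np.linspace(0.8, 0.1, n_genes)  # high abundance -> low variance
        y = mean[:, None] + rng.normal(size=(n_genes, len(X))) * sd[:, None]
        lcpm = pd.DataFrame(y, index=[f"G{i:05d}" for i in range(n_genes)],
                            columns=X.index)
        w = precision_weights(lcpm, small_design)
        mean_w = w.mean(axis=1).to_numpy()
        # weights along the trend rise with abundance (check decile means)
        deciles = np.array_split(mean_w, 10)
        means = [d.mean() for d in deciles]
        assert all(b > a for a, b in zip(means, means[1:]))


class TestBenjaminiHochberg:
    def test_worked_stepup_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            benjamini_hochberg([0.1, np.nan])

    def test_matches_definition_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ours = benjamini_hochberg(p)
            np.testing.assert_allclose(ours, bh_stepup(p), atol=1e-12)
            np.testing.assert_allclose(
                ours, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )


class TestSharedResponseFit:
    def test_recovers_planted_signal(self, planted_simulation):
        counts, design, truth = planted_simulation
        result = run_de(counts, design)
        planted = truth.planted_log2fc[truth.planted_log2fc != 0]
        found = result.reindex(planted.index).dropna()
        called = found[(found["fdr"] < 0.05) & (found["log2fc"].abs() > 0.5)]
        assert len(called) / len(planted) >= 0.9
        signs_agree = np.sign(called["log2fc"]) == np.sign(planted.reindex(called.index))
        assert signs_agree.all()
        # effect estimates unbiased
        err = found["log2fc"] - planted.reindex(found.index)
        assert abs(err.mean()) < 0.05

    def test_full_shrinkage_limit(self, planted_simulation):
        counts, design, _ = planted_simulation
        lcpm = log_cpm(counts, tmm_factors(counts))
        w = precision_weights(lcpm, design)
        result = fit_shared_response(lcpm, w, design, prior_df=np.inf)
        # with d0 -> inf all genes share one posterior sd: t / (lfc/se) constant
        X = build_design_matrix(design).to_numpy()
        W = w.to_numpy()
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
        se = np.sqrt(np.linalg.inv(XtWX)[:, -1, -1])
        ratio = result["log2fc"] / (se * result["moderated_t"])
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_permuting_ph_labels_destroys_calls(self, planted_simulation):
        counts, design, truth = planted_simulation
        rng = np.random.default_rng(0)
        shuffled = design.copy()
        for line in shuffled["cell_line"].unique():
            idx = shuffled.index[shuffled["cell_line"] == line]
            shuffled.loc[idx, "ph"] = rng.permutation(shuffled.loc[idx, "ph"].to_numpy())
        result = run_de(counts, shuffled)
        planted_genes = truth.planted_log2fc[truth.planted_log2fc != 0].index
        called = result.reindex(planted_genes)["call"].ne("ns").mean()
        assert called <= 0.05

    def test_calls_respect_both_thresholds(self, planted_simulation):
        counts, design, _ = planted_simulation
        result = run_de(counts, design)
        up = result[result["call"] == "up"]
        down = result[result["call"] == "down"]
        assert ((up["fdr"] < 0.05) & (up["log2fc"] > 0.5)).all()
        assert ((down["fdr"] < 0.05) & (down["log2fc"] < -0.5)).all()

    def test_rank_deficient_design_rejected(self, small_design):
        broken = small_design.copy()
        broken["ph"] = "acid"
        with pytest.raises(ValueError, match="pH|rank|present"):
            build_design_matrix(broken)
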