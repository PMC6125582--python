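"""Preprocessing stages against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from coexmod.preprocess import (
    AngleBasedOutlierDetector,
    RNASeqPreprocessor,
    abof_report,
    abof_scores,
    cov_filter,
    cpm,
    filter_low_counts,
    logcpm,
    low_count_thresholds,
    remove_batch_effect,
)


class TestLowCountFilter:
    def test_all_zero_gene_removed(self, toy_counts):
        counts = toy_counts.copy()
        counts.loc["gz"] = 0
        kept, removed = filter_low_counts(counts, min_samples=5)
        assert "gz" in removed and "gz" not in kept.index

    def test_high_count_gene_survives_strictest_threshold(self, toy_counts):
        counts = toy_counts.copy()
        counts.loc["ghi"] = 7  # >= 7 reads everywhere passes any threshold
        kept, _ = filter_low_counts(counts, min_samples=15)
        assert "ghi" in kept.index

    def test_threshold_interpolation_against_enumeration(self):
        """20 hand-set library sizes; thresholds re-derived by explicit
        enumeration of the rank interpolation, and a straddling gene
        classified accordingly."""
        lib = pd.Series(
            np.linspace(1e5, 2e6, 20), index=[f"s{j}" for j in range(20)]
        )
        t = low_count_thresholds(lib)
        expected = np.floor(2 + 5 * np.arange(20) / 19 + 0.5).astype(int)
        assert (t.to_numpy() == expected).all()

        # gene with exactly t_j reads in 15 samples is kept; one read
        # fewer in a single sample drops it to 14 qualifying samples
        counts = pd.DataFrame(0, index=["edge", "below"], columns=lib.index)
        counts.loc["edge", lib.index[:15]] = t[lib.index[:15]]
        counts.loc["below", lib.index[:15]] = t[lib.index[:15]]
        counts.loc["below", lib.index[0]] = t.iloc[0] - 1
        kept, removed = filter_low_counts(counts, library_sizes=lib)
        assert "edge" in kept.index and "below" in removed

    def test_idempotent(self, toy_counts):
        lib = toy_counts.sum(axis=0)
        once, _ = filter_low_counts(toy_counts, min_samples=5, library_sizes=lib)
        twice, removed2 = filter_low_counts(once, min_samples=5, library_sizes=lib)
        pd.testing.assert_frame_equal(once, twice)
        assert removed2 == []

    def test_min_samples_exceeding_cohort_errors(self, toy_counts):
        with pytest.raises(ValueError, match="min_samples"):
            filter_low_counts(toy_counts, min_samples=21)


class TestLogCPM:
    def test_closed_form_values(self):
        counts = pd.DataFrame({"s": [0, 999]}, index=["g0", "g1"])
        lib = pd.Series({"s": 1e6})
        expr = logcpm(counts, lib)
        assert expr.loc["s", "g0"] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6))
        assert expr.loc["s", "g1"] == pytest.approx(9.965, abs=1e-3)

    def test_scale_invariance_for_large_counts(self, rng):
        counts = pd.DataFrame(
            rng.integers(500, 5000, size=(20, 5)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(5)],
        )
        a = logcpm(counts)
        b = logcpm(counts * 2)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-3

    def test_zero_library_size_names_sample(self):
        counts = pd.DataFrame({"good": [5, 5], "bad": [0, 0]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="bad"):
            logcpm(counts)


class TestABOF:
    def test_matches_brute_force(self, rng):
        from _oracles import abof_brute_force

        X = pd.DataFrame(rng.normal(size=(18, 6)))
        fast = abof_scores(X, standardize=False).to_numpy()
        slow = abof_brute_force(X.to_numpy())
        assert np.abs(fast - slow).max() < 1e-10

    def test_three_samples_all_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 4)))
        assert (abof_scores(X, standardize=False) == 0).all()

    def test_far_point_has_minimum_abof(self, rng):
        cluster = rng.normal(size=(19, 2))
        X = pd.DataFrame(np.vstack([cluster, [30.0, 30.0]]))
        scores = abof_scores(X, standardize=False)
        assert scores.idxmin() == 19

    def test_permutation_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"s{i}" for i in range(12)])
        perm = list(rng.permutation(X.index))
        a = abof_scores(X)
        b = abof_scores(X.loc[perm])
        assert np.allclose(a.loc[perm].to_numpy(), b.to_numpy())

    def test_detector_flags_planted_outlier(self, small_cohort):
        kept, _ = filter_low_counts(small_cohort.counts)
        expr = logcpm(kept)
        det = AngleBasedOutlierDetector().fit(expr)
        assert det.outliers_ == small_cohort.truth.outliers

    def test_degenerate_pairs_error(self):
        X = pd.DataFrame([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            abof_scores(X, standardize=False)

    def test_report_threshold_is_resolved_minimum(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 8)))
        report = abof_report(X, threshold=0.001, relative_threshold=0.1)
        expected = min(0.001, 0.1 * float(report.abof.median()))
        assert report.threshold == pytest.approx(expected)


class TestBatchRemoval:
    def test_single_batch_is_identity(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 4)))
        batch = pd.Series(["A"] * 10, index=expr.index)
        pd.testing.assert_frame_equal(remove_batch_effect(expr, batch), expr)

    def test_pure_offset_removed_exactly(self):
        batch = pd.Series(["A"] * 5 + ["B"] * 5)
        gene = 3.0 + 2.5 * (batch == "B").to_numpy()
        expr = pd.DataFrame({"g": gene})
        out = remove_batch_effect(expr, batch)
        assert np.allclose(out["g"], out["g"].iloc[0])

    def test_against_normal_equations_oracle(self, rng):
        """10 samples, 3 genes, known batch offsets and a covariate; the
        correction equals an explicit normal-equations solve."""
        n = 10
        batch = pd.Series(["A"] * 4 + ["B"] * 6)
        covariate = pd.DataFrame({"age": rng.normal(size=n)})
        expr = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("xyz"))
        expr.loc[batch == "B"] += [1.0, -2.0, 0.5]

        out = remove_batch_effect(expr, batch, covariate)

        B = np.where(batch == "A", 1.0, -1.0).reshape(-1, 1)
        X = np.hstack([np.ones((n, 1)), covariate.to_numpy(), B])
        beta = np.linalg.solve(X.T @ X, X.T @ expr.to_numpy())
        component = B @ beta[[2]]
        component -= component.mean(axis=0)
        expected = expr.to_numpy() - component
        assert np.abs(out.to_numpy() - expected).max() < 1e-10

    def test_grand_mean_preserved(self, rng):
        expr = pd.DataFrame(rng.normal(size=(13, 6)))
        batch = pd.Series(["A"] * 3 + ["B"] * 4 + ["C"] * 6)
        out = remove_batch_effect(expr, batch)
        assert np.abs(out.mean(axis=0) - expr.mean(axis=0)).max() < 1e-8

    def test_confounded_design_errors(self):
        batch = pd.Series(["A"] * 5 + ["B"] * 5)
        cov = pd.DataFrame({"dup": (batch == "B").astype(float)})
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="singular"):
            remove_batch_effect(expr, batch, cov)

    def test_small_batch_level_errors(self):
        batch = pd.Series(["A"] * 9 + ["B"])
        expr = pd.DataFrame(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            remove_batch_effect(expr, batch)


class TestCovFilter:
    def test_constant_gene_retained(self):
        mat = pd.DataFrame({"const": [5.0] * 6, "noisy": [0.1, 9, 0.1, 9, 0.1, 9]})
        keep, report = cov_filter(mat, threshold=0.8)
        assert keep["const"] and not keep["noisy"]

    def test_two_point_gene_arithmetic(self):
        # values {1, 3}: mean 2, sample sd sqrt(2) -> COV 0.707 <= 0.8
        mat = pd.DataFrame({"g": [1.0, 3.0]})
        keep, report = cov_filter(mat, threshold=0.8)
        assert keep["g"]
        assert report.loc["g", "cov"] == pytest.approx(np.sqrt(2) / 2)

    def test_zero_threshold_keeps_only_constants(self, rng):
        mat = pd.DataFrame({"const": np.ones(8), "var": rng.uniform(1, 2, 8)})
        keep, _ = cov_filter(mat, threshold=0.0)
        assert keep["const"] and not keep["var"]

    def test_zero_mean_gene_removed_with_reason(self):
        mat = pd.DataFrame({"zero": np.zeros(5), "ok": np.ones(5)})
        keep, report = cov_filter(mat)
        assert not keep["zero"]
        assert report.loc["zero", "reason"] == "zero-mean"


class TestPreprocessorChain:
    def test_gene_count_arithmetic(self, small_cohort):
        pre = RNASeqPreprocessor()
        expr = pre.fit_transform(small_cohort.counts, small_cohort.phenotypes)
        prov = pre.provenance_
        assert (
            prov["n_genes_in"]
            - prov["low_count"]["n_removed"]
            - prov["high_cov"]["n_removed"]
            == prov["n_genes_out"]
            == expr.shape[1]
        )
        assert prov["normalized_genes"] == prov["n_genes_in"] - prov["low_count"]["n_removed"]

    def test_planted_outlier_removed_and_recorded(self, small_cohort):
        pre = RNASeqPreprocessor()
        expr = pre.fit_transform(small_cohort.counts, small_cohort.phenotypes)
        assert pre.removed_outliers_ == small_cohort.truth.outliers
        assert not set(pre.removed_outliers_) & set(expr.index)

    def test_finite_output(self, small_cohort):
        expr = RNASeqPreprocessor().fit_transform(
            small_cohort.counts, small_cohort.phenotypes
        )
        assert np.isfinite(expr.to_numpy()).all()
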