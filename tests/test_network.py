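"""Network construction and module detection against oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexmod.network import (
    CoexpressionModuleDetector,
    average_linkage,
    correlation_adjacency,
    dynamic_tree_cut,
    hard_threshold,
    tom_dissimilarity,
    tune_hard_threshold,
)


from _oracles import tom_brute_force


def block_dissimilarity(sizes, within, between, rng, jitter=0.02):
    n = sum(sizes)
    D = np.full((n, n), between)
    start = 0
    for s in sizes:
        D[start : start + s, start : start + s] = within
        start += s
    D += rng.uniform(0, jitter, (n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    return D


class TestAdjacency:
    def test_anticorrelated_genes_fully_connected(self):
        x = np.linspace(0, 1, 8)
        expr = pd.DataFrame({"a": x, "b": -x})
        adj = correlation_adjacency(expr)
        assert adj[0, 1] == pytest.approx(1.0)
        assert adj[0, 0] == 0.0

    def test_null_mean_absolute_correlation(self, rng):
        """Independent normals: E|r| ~ sqrt(2 / (pi * n))."""
        n = 1000
        expr = rng.standard_normal((n, 40))
        adj = correlation_adjacency(expr)
        off = adj[np.triu_indices(40, 1)]
        assert off.mean() == pytest.approx(np.sqrt(2 / (np.pi * n)), rel=0.15)

    def test_hand_computed_three_genes(self):
        expr = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10], "c": [5.0, 3, 4, 1, 2]}
        )
        adj = correlation_adjacency(expr)
        expected_ac = abs(np.corrcoef(expr["a"], expr["c"])[0, 1])
        assert adj[0, 1] == pytest.approx(1.0)
        assert adj[0, 2] == pytest.approx(expected_ac)

    def test_zero_variance_gene_errors(self):
        expr = pd.DataFrame({"flat": [1.0, 1, 1, 1], "ok": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="flat"):
            correlation_adjacency(expr)


class TestHardThreshold:
    def test_tau_zero_is_identity(self, rng):
        A = rng.uniform(size=(6, 6))
        assert np.array_equal(hard_threshold(A, 0.0), A)

    def test_tau_one_keeps_only_exact_ones(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        B = np.array([[0.0, 0.999], [0.999, 0.0]])
        assert hard_threshold(A, 1.0)[0, 1] == 1.0
        assert hard_threshold(B, 1.0)[0, 1] == 0.0

    def test_printed_toy_matrix(self):
        A = np.array(
            [
                [0.0, 0.1, 0.2, 0.6],
                [0.1, 0.0, 0.19, 0.3],
                [0.2, 0.19, 0.0, 0.05],
                [0.6, 0.3, 0.05, 0.0],
            ]
        )
        out = hard_threshold(A, 0.2)
        assert out[0, 1] == 0.0 and out[1, 2] == 0.0
        assert out[0, 2] == 0.2 and out[0, 3] == 0.6 and out[1, 3] == 0.3

    def test_binarize_flag(self):
        A = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert hard_threshold(A, 0.2, binarize=True)[0, 1] == 1.0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            hard_threshold(np.zeros((2, 2)), 1.5)


class TestTOM:
    def test_isolated_perfect_pair(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        D = tom_dissimilarity(A)
        assert D[0, 1] == pytest.approx(0.0)

    def test_disconnected_pair_maximally_dissimilar(self):
        A = np.zeros((4, 4))
        A[2, 3] = A[3, 2] = 0.5
        D = tom_dissimilarity(A)
        assert D[0, 1] == pytest.approx(1.0)

    def test_five_node_weighted_graph_brute_force(self, rng):
        A = rng.uniform(size=(5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        D = tom_dissimilarity(A)
        assert np.abs(D - tom_brute_force(A)).max() < 1e-12

    def test_random_adjacencies_brute_force(self, rng):
        """TOM equals the O(n^3) definition on random 20-gene graphs."""
        for _ in range(25):
            A = rng.uniform(size=(20, 20)) * (rng.random((20, 20)) < 0.5)
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            D = tom_dissimilarity(A)
            assert np.abs(D - tom_brute_force(A)).max() < 1e-10
            assert np.allclose(D, D.T)
            assert (D >= 0).all() and (D <= 1).all()

    def test_denominator_positive_for_valid_adjacency(self, rng):
        """k_i >= a_ij forces min(k_i, k_j) + 1 - a_ij >= 1, so the
        degenerate-denominator guard can only fire on invalid input;
        check the bound on extreme valid graphs."""
        for A in (
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.ones((5, 5)) - np.eye(5),
            np.zeros((4, 4)),
        ):
            k = A.sum(axis=1)
            denom = np.minimum.outer(k, k) + 1 - A
            off = ~np.eye(len(A), dtype=bool)
            assert (denom[off] >= 1 - 1e-12).all()
            assert np.isfinite(tom_dissimilarity(A)).all()


class TestLinkage:
    def test_identical_genes_merge_first_at_zero(self):
        D = np.array(
            [[0.0, 0.0, 0.9], [0.0, 0.0, 0.9], [0.9, 0.9, 0.0]]
        )
        Z = average_linkage(D)
        assert Z[0, 2] == pytest.approx(0.0)
        assert sorted(Z[0, :2]) == [0, 1]

    def test_manual_upgma_four_leaves(self):
        """Hand agglomeration: (a,b) at 0.2; (c,d) at 0.3; join at mean."""
        D = np.array(
            [
                [0.0, 0.2, 0.8, 0.9],
                [0.2, 0.0, 0.7, 0.8],
                [0.8, 0.7, 0.0, 0.3],
                [0.9, 0.8, 0.3, 0.0],
            ]
        )
        Z = average_linkage(D)
        assert Z[0, 2] == pytest.approx(0.2)
        assert Z[1, 2] == pytest.approx(0.3)
        assert Z[2, 2] == pytest.approx((0.8 + 0.9 + 0.7 + 0.8) / 4)

    def test_leaf_order_permutation_preserves_heights(self, rng):
        D = rng.uniform(0.2, 1.0, size=(12, 12))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        perm = rng.permutation(12)
        h1 = np.sort(average_linkage(D)[:, 2])
        h2 = np.sort(average_linkage(D[np.ix_(perm, perm)])[:, 2])
        assert np.allclose(h1, h2)


class TestDynamicTreeCut:
    def test_two_separated_blocks(self, rng):
        D = block_dissimilarity([50, 60], 0.1, 0.9, rng)
        labels = dynamic_tree_cut(average_linkage(D), D, min_module_size=30)
        assert set(labels) == {1, 2}
        assert adjusted_rand_score(np.repeat([1, 2], [50, 60]), labels) == 1.0

    def test_sub_threshold_block_unassigned_or_absorbed(self, rng):
        D = block_dissimilarity([50, 10], 0.1, 0.9, rng)
        labels = dynamic_tree_cut(average_linkage(D), D, min_module_size=30)
        assert len(set(labels) - {0}) == 1

    def test_nested_blocks_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            D = np.full((150, 150), 0.9)
            D[:100, :100] = 0.5
            for s in range(0, 150, 50):
                D[s : s + 50, s : s + 50] = 0.15
            D += rng.uniform(0, 0.02, D.shape)
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            labels = dynamic_tree_cut(average_linkage(D), D, min_module_size=30)
            hits += adjusted_rand_score(np.repeat([1, 2, 3], 50), labels) >= 0.9
        assert hits >= 9

    def test_partition_and_size_floor(self, rng):
        D = block_dissimilarity([40, 35, 45], 0.2, 0.9, rng)
        labels = dynamic_tree_cut(average_linkage(D), D, min_module_size=30)
        assert labels.shape == (120,)
        sizes = np.bincount(labels)[1:]
        assert (sizes[sizes > 0] >= 30).all()

    def test_labels_ordered_by_size(self, rng):
        D = block_dissimilarity([60, 40], 0.1, 0.9, rng)
        labels = dynamic_tree_cut(average_linkage(D), D, min_module_size=30)
        sizes = [np.sum(labels == lab) for lab in sorted(set(labels) - {0})]
        assert sizes == sorted(sizes, reverse=True)

    def test_min_size_exceeding_genes_errors(self, rng):
        D = block_dissimilarity([10], 0.1, 0.9, rng)
        with pytest.raises(ValueError):
            dynamic_tree_cut(average_linkage(D), D, min_module_size=11)


class TestTuning:
    def test_singleton_grid_returns_it(self, small_cohort):
        from coexmod.preprocess import filter_low_counts, logcpm

        kept, _ = filter_low_counts(small_cohort.counts)
        expr = logcpm(kept)
        tau, labels, report = tune_hard_threshold(expr, [0.2], target_mean_size=100)
        assert tau == 0.2
        assert len(report) == 1

    def test_tie_breaks_toward_smaller_tau(self, rng, monkeypatch):
        """Two grid points with identical objective -> smaller tau wins."""
        import coexmod.network as net

        expr = pd.DataFrame(rng.standard_normal((30, 40)))
        calls = {}

        def fake_cut(Z, D, **kwargs):
            labels = np.zeros(40, dtype=int)
            labels[:30] = 1  # same partition whatever tau
            return labels

        monkeypatch.setattr(net, "dynamic_tree_cut", fake_cut)
        tau, _, report = net.tune_hard_threshold(
            expr, [0.3, 0.1], target_mean_size=100
        )
        assert tau == 0.1

    def test_planted_sizes_drive_selection(self):
        """On a planted cohort the tuned threshold lands mean module size
        in a band around the target."""
        import coexmod as cm
        from coexmod.preprocess import RNASeqPreprocessor

        config = cm.SimulationConfig(
            n_samples=160,
            n_genes=800,
            module_sizes=(150,) * 4,
            rho=0.6,
            frac_low_count=0.1,
            frac_high_cov=0.05,
            seed=4,
        )
        cohort = cm.generate_cohort(config)
        expr = RNASeqPreprocessor().fit_transform(cohort.counts, cohort.phenotypes)
        tau, labels, report = tune_hard_threshold(
            expr, [0.1, 0.2, 0.3], target_mean_size=150
        )
        sizes = np.bincount(labels)[1:]
        sizes = sizes[sizes > 0]
        assert 100 <= sizes.mean() <= 200

    def test_empty_grid_errors(self, rng):
        with pytest.raises(ValueError):
            tune_hard_threshold(pd.DataFrame(rng.standard_normal((10, 5))), [])


class TestDetectorEstimator:
    def test_recovers_planted_modules(self, small_cohort):
        from coexmod.preprocess import RNASeqPreprocessor

        expr = RNASeqPreprocessor().fit_transform(
            small_cohort.counts, small_cohort.phenotypes
        )
        det = CoexpressionModuleDetector(tau=0.2).fit(expr)
        truth = small_cohort.truth.module_labels.reindex(expr.columns).fillna(0)
        mask = (truth > 0).to_numpy() & (det.labels_ > 0)
        assert adjusted_rand_score(truth.to_numpy()[mask], det.labels_[mask]) >= 0.9
        assert set(det.gene_sets_) == {f"M{m}" for m in det.module_sizes_}

    def test_edge_monotonicity_in_tau(self, small_cohort):
        from coexmod.preprocess import filter_low_counts, logcpm

        kept, _ = filter_low_counts(small_cohort.counts)
        expr = logcpm(kept.iloc[:100])
        base = correlation_adjacency(expr)
        degrees = [hard_threshold(base, t).sum(axis=1) for t in (0.1, 0.2, 0.3)]
        assert (degrees[0] >= degrees[1]).all() and (degrees[1] >= degrees[2]).all()

    def test_sklearn_params_round_trip(self):
        det = CoexpressionModuleDetector(tau=0.3, min_module_size=40)
        params = det.get_params()
        clone = CoexpressionModuleDetector(**params)
        assert clone.get_params() == params
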