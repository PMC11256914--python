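import numpy as np
import pytest
from scipy import stats

from phylaugment.otu_io import TaxonomyMap
from phylaugment.taxonn import (
    PhylumPartition,
    TaxonnConfig,
    TaxonnClassifier,
    assign_phylum_clusters,
    cumulative_correlation,
    default_class_weights,
    integrated_gradients,
    order_features,
    predict_proba,
    prepare_blocks,
    spearman_matrix,
    train_ensemble,
    weighted_cross_entropy,
)


def _tax(phyla: list[str]) -> TaxonomyMap:
    return TaxonomyMap(entries={
        f"o{i}": {"kingdom": "Bacteria", "phylum": ph, "genus": f"g{i}"}
        for i, ph in enumerate(phyla)
    })


class TestAssignPhylumClusters:
    def test_three_phyla_no_overflow(self):
        phyla = ["A"] * 5 + ["B"] * 3 + ["C"] * 2
        part = assign_phylum_clusters([f"o{i}" for i in range(10)],
                                      _tax(phyla), top_k=3)
        assert [name for name, _ in part.clusters] == ["A", "B", "C"]
        assert part.overflow.size == 0

    def test_minor_phylum_goes_to_overflow(self):
        phyla = ["A"] * 5 + ["B"] * 3 + ["C"] * 2 + ["D"] * 1
        with pytest.warns(UserWarning, match="excluded"):
            part = assign_phylum_clusters([f"o{i}" for i in range(11)],
                                          _tax(phyla), top_k=3)
        assert list(part.overflow) == [10]

    def test_keep_other_builds_extra_cluster(self):
        phyla = ["A"] * 4 + ["B"] * 3 + ["C"] * 2 + ["D"] * 1
        part = assign_phylum_clusters([f"o{i}" for i in range(10)],
                                      _tax(phyla), top_k=2, keep_other=True)
        assert [n for n, _ in part.clusters] == ["A", "B", "Other"]
        assert sorted(part.clusters[2][1]) == [7, 8, 9]

    def test_sizes_match_counting_oracle(self, sim_small):
        table, tax, _ = sim_small
        part = assign_phylum_clusters(table.otu_ids, tax, top_k=3)
        for name, idx in part.clusters:
            expected = sum(tax.phylum(o) == name for o in table.otu_ids)
            assert len(idx) == expected

    def test_missing_otu_listed(self):
        with pytest.raises(ValueError, match="oX"):
            assign_phylum_clusters(["o0", "oX"], _tax(["A"]), top_k=1)


class TestSpearmanMatrix:
    def test_comonotone_pair(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2])
        rho = spearman_matrix(x, np.array([0, 1]))
        assert rho[0, 1] == pytest.approx(1.0)

    def test_antimonotone_pair(self):
        x = np.column_stack([np.arange(10.0), -np.arange(10.0)])
        rho = spearman_matrix(x, np.array([0, 1]))
        assert rho[0, 1] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random((20, 5))
        rho = spearman_matrix(x, np.arange(5))
        ranks = np.column_stack([stats.rankdata(x[:, j]) for j in range(5)])
        expected = np.corrcoef(ranks, rowvar=False)
        np.testing.assert_allclose(rho, expected, atol=1e-10)

    def test_constant_column_convention(self):
        x = np.column_stack([np.arange(8.0), np.full(8, 3.0)])
        rho = spearman_matrix(x, np.array([0, 1]))
        assert rho[0, 1] == 0.0 and rho[1, 1] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spearman_matrix(np.ones((2, 4)), np.arange(4))


class TestCumulativeCorrelation:
    def test_all_ones(self):
        assert cumulative_correlation(np.ones((4, 4))) == pytest.approx(1.0)

    def test_identity_annihilates(self):
        out = cumulative_correlation(np.eye(3))
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_product_root_example(self):
        rho = np.array([[1.0, 0.5, 0.5],
                        [0.5, 1.0, 0.25],
                        [0.5, 0.25, 1.0]])
        out = cumulative_correlation(rho)
        assert out[0] == pytest.approx((1 * 0.5 * 0.5) ** (1 / 3), abs=1e-4)

    def test_matches_direct_product_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.integers(2, 21)
            a = rng.uniform(-1, 1, size=(p, p))
            rho = (a + a.T) / 2
            np.fill_diagonal(rho, 1.0)
            expected = np.array([
                np.prod(np.abs(rho[j])) ** (1.0 / p) for j in range(p)
            ])
            np.testing.assert_allclose(cumulative_correlation(rho), expected,
                                       atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(-1, 1, (6, 6))
        rho = (a + a.T) / 2
        np.fill_diagonal(rho, 1.0)
        perm = rng.permutation(6)
        base = cumulative_correlation(rho)
        permuted = cumulative_correlation(rho[np.ix_(perm, perm)])
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)


class TestOrderFeatures:
    def test_simple_sort(self):
        np.testing.assert_array_equal(order_features([0.2, 0.9, 0.5]),
                                      [1, 2, 0])

    def test_ties_keep_original_order(self):
        np.testing.assert_array_equal(order_features([0.5, 0.5, 0.5]),
                                      [0, 1, 2])

    def test_matches_stable_argsort_oracle(self):
        rng = np.random.default_rng(3)
        coeffs = np.round(rng.random(100), 2)  # ties likely
        perm = order_features(coeffs)
        expected = sorted(range(100), key=lambda j: (-coeffs[j], j))
        np.testing.assert_array_equal(perm, expected)

    def test_ordering_idempotent(self):
        rng = np.random.default_rng(4)
        coeffs = rng.random(30)
        once = order_features(coeffs)
        again = order_features(coeffs[once])
        np.testing.assert_array_equal(again, np.arange(30))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            order_features([0.1, np.nan])


class TestWeightedCrossEntropy:
    def test_unit_weights_reduce_to_plain_ce(self):
        probs = [0.8, 0.3, 0.6, 0.4]
        labels = [1, 0, 1, 0]
        expected = -np.mean([np.log(0.8), np.log(0.7), np.log(0.6), np.log(0.6)])
        assert weighted_cross_entropy(probs, labels) == pytest.approx(expected)

    def test_log_half(self):
        assert weighted_cross_entropy([0.5], [1]) == pytest.approx(0.6931, abs=1e-4)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(0.01, 0.99, 16)
        labels = rng.integers(0, 2, 16)
        w0, w1 = 0.7, 1.3
        expected = -np.mean([
            (w1 * np.log(p) if y else w0 * np.log(1 - p))
            for p, y in zip(probs, labels)
        ])
        got = weighted_cross_entropy(probs, labels, (w0, w1))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_default_weights_balance_to_two(self):
        w0, w1 = default_class_weights(np.array([0, 0, 0, 1]))
        assert w0 + w1 == pytest.approx(2.0)
        assert w1 == pytest.approx(3 * w0)  # rarer class weighted up

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy([], [])


def _toy_blocks(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    b1 = rng.normal(size=(n, 8)) + y[:, None] * 1.5
    b2 = rng.normal(size=(n, 6))
    return [b1, b2], y


class TestEnsemble:
    def test_model_holds_one_bundle_per_cluster(self):
        blocks, y = _toy_blocks()
        model = train_ensemble(blocks + [np.zeros((40, 7))], y,
                               TaxonnConfig(epochs=2, seed=0))
        assert model.n_clusters == 3

    def test_determinism(self):
        blocks, y = _toy_blocks()
        cfg = TaxonnConfig(epochs=3, seed=5)
        m1 = train_ensemble(blocks, y, cfg)
        m2 = train_ensemble(blocks, y, cfg)
        np.testing.assert_array_equal(m1.merge["W"], m2.merge["W"])
        for a, b in zip(m1.blocks, m2.blocks):
            np.testing.assert_array_equal(a["params"]["W"], b["params"]["W"])

    def test_narrow_cluster_uses_dense_fallback(self):
        blocks, y = _toy_blocks()
        with pytest.warns(UserWarning, match="dense"):
            model = train_ensemble([blocks[0], np.ones((40, 3))], y,
                                   TaxonnConfig(epochs=1, seed=0))
        assert model.blocks[1]["kind"] == "dense"

    def test_probabilities_valid_and_deterministic(self):
        blocks, y = _toy_blocks()
        model = train_ensemble(blocks, y, TaxonnConfig(epochs=5, seed=1))
        p1 = predict_proba(model, blocks)
        p2 = predict_proba(model, blocks)
        np.testing.assert_array_equal(p1, p2)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_learns_separable_blocks(self):
        blocks, y = _toy_blocks(n=60, seed=2)
        model = train_ensemble(blocks, y, TaxonnConfig(epochs=60, seed=2))
        p = predict_proba(model, blocks)
        assert ((p > 0.5).astype(int) == y).mean() > 0.9

    def test_layout_mismatch_rejected(self):
        blocks, y = _toy_blocks()
        model = train_ensemble(blocks, y, TaxonnConfig(epochs=1, seed=0))
        with pytest.raises(ValueError, match="width"):
            predict_proba(model, [blocks[0], np.zeros((40, 99))])


class TestTaxonnClassifier:
    def test_strong_effect_benchmark_auc(self, sim_small):
        """Planted 4-fold effect is recovered well above chance."""
        table, tax, _ = sim_small
        part = assign_phylum_clusters(table.otu_ids, tax, top_k=3)
        rng = np.random.default_rng(0)
        order = rng.permutation(table.n_samples)
        X, y = table.values[order], table.labels[order]
        n_tr = 80
        clf = TaxonnClassifier(part, TaxonnConfig(epochs=150, standardize=True,
                                                  seed=0))
        clf.fit(X[:n_tr], y[:n_tr])
        p = clf.predict_proba(X[n_tr:])[:, 1]
        from phylaugment.eval_metrics import binary_metrics
        assert binary_metrics(p, y[n_tr:]).auc > 0.6

    def test_prepare_blocks_reapplies_ordering(self, sim_small):
        table, tax, _ = sim_small
        part = assign_phylum_clusters(table.otu_ids, tax, top_k=3)
        blocks, ordering = prepare_blocks(table.values, part)
        for (name, idx), perm, blk in zip(part.clusters,
                                          ordering.permutations, blocks):
            np.testing.assert_array_equal(table.values[:, idx][:, perm], blk)
            coeffs = ordering.cumulative_coefficients[
                [n for n, _ in part.clusters].index(name)]
            assert all(coeffs[i] >= coeffs[i + 1] for i in range(len(coeffs) - 1))


class TestIntegratedGradients:
    def _fitted(self):
        blocks, y = _toy_blocks(n=50, seed=3)
        X = np.hstack(blocks)
        part = PhylumPartition(
            clusters=[("A", np.arange(8)), ("B", np.arange(8, 14))],
            overflow=np.array([], dtype=int))
        clf = TaxonnClassifier(part, TaxonnConfig(epochs=30, seed=3))
        clf.fit(X, y)
        return clf.model, X

    def test_zero_at_baseline(self):
        model, X = self._fitted()
        attr = integrated_gradients(model, X[0], baseline=X[0], steps=16)
        np.testing.assert_allclose(attr, 0.0, atol=1e-12)

    def test_completeness_and_convergence(self):
        model, X = self._fitted()
        sample, baseline = X[1], np.zeros_like(X[1])
        f = lambda v: predict_proba(model, v[None, :])[0]
        target = f(sample) - f(baseline)
        residuals = []
        for steps in (64, 128):
            attr = integrated_gradients(model, sample, baseline, steps=steps)
            residuals.append(abs(attr.sum() - target))
        assert residuals[1] <= residuals[0] + 1e-9
        assert residuals[1] <= 0.02 * max(abs(target), 1e-3)

    def test_too_few_steps_rejected(self):
        model, X = self._fitted()
        with pytest.raises(ValueError):
            integrated_gradients(model, X[0], steps=4)
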