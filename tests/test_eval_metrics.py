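import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from phylaugment.eval_metrics import (
    binary_metrics,
    chao1_index,
    compare_distributions,
    counts_from_relative,
    cross_validate,
    percentile_ci,
    shannon_index,
    sparsity,
    train_test_split,
)
from phylaugment.otu_io import OtuTable


class TestSparsity:
    def test_half_zero_row(self):
        t = OtuTable(values=np.array([[0.0, 0.0, 1.0, 3.0]]), sample_ids=["a"],
                     otu_ids=list("wxyz"), mode="counts")
        mean, (lo, hi) = sparsity(t)
        assert mean == lo == hi == 0.5

    def test_matches_brute_force(self, sim_small):
        table, _, _ = sim_small
        mean, (lo, hi) = sparsity(table)
        per_row = [(row == 0).sum() / len(row) for row in table.values]
        assert mean == pytest.approx(np.mean(per_row))
        assert (lo, hi) == (min(per_row), max(per_row))


class TestShannon:
    def test_uniform_is_log_k(self):
        assert shannon_index(np.full(4, 0.25)) == pytest.approx(np.log(4), abs=1e-4)

    def test_single_taxon_zero(self):
        assert shannon_index([0.0, 1.0, 0.0]) == 0.0

    def test_direct_summation_example(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_uniform_is_maximal_and_zero_padding_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.dirichlet(np.ones(6))
        assert shannon_index(x) <= shannon_index(np.full(6, 1 / 6)) + 1e-12
        padded = np.concatenate([x, np.zeros(5)])
        assert shannon_index(padded) == pytest.approx(shannon_index(x))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([-0.1, 1.1])


class TestChao1:
    def test_no_singletons_equals_richness(self):
        x = np.array([0, 5, 3, 2, 0, 7])
        assert chao1_index(x) == 4  # S_obs, F1=0

    def test_formula_example(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
        x = np.array([1, 1, 1, 1, 2, 2, 3, 4, 5, 6])
        assert chao1_index(x) == pytest.approx(12.0)

    def test_all_zero_sample(self):
        assert chao1_index(np.zeros(8)) == 0.0

    def test_never_below_observed_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.poisson(1.0, size=30)
            assert chao1_index(x) >= (x > 0).sum()

    def test_non_integer_rejected_with_hint(self, small_table):
        with pytest.raises(ValueError, match="integer"):
            chao1_index(small_table.values[0])
        counts = counts_from_relative(small_table, depth=1000)
        assert counts.mode == "counts"
        assert chao1_index(counts.values[0]) >= 0


class TestCompareDistributions:
    def test_identical_multisets_p_one(self):
        a = [1.0, 2.0, 3.0, 3.0]
        assert compare_distributions(a, list(a)) == pytest.approx(1.0)

    def test_fully_separated_small(self):
        a = np.arange(20, dtype=float)
        b = a + 100
        assert compare_distributions(a, b) < 0.001

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        p = compare_distributions(a, b)
        # permutation distribution of the rank-sum statistic
        from scipy import stats
        pooled = np.concatenate([a, b])
        obs = stats.rankdata(pooled)[:15].sum()
        null = []
        perm_rng = np.random.default_rng(6)
        for _ in range(4000):
            perm = perm_rng.permutation(pooled)
            null.append(stats.rankdata(perm)[:15].sum())
        null = np.asarray(null)
        mu = null.mean()
        p_perm = (np.abs(null - mu) >= abs(obs - mu)).mean()
        assert abs(p - p_perm) < 0.02

    def test_symmetric(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=25), rng.normal(0.3, 1, 30)
        assert compare_distributions(a, b) == pytest.approx(
            compare_distributions(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestBinaryMetrics:
    def test_perfect_separation(self):
        r = binary_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_constant_scores_tie_corrected(self):
        r = binary_metrics([0.7] * 6, [1, 0, 1, 0, 1, 0])
        assert r.auc == pytest.approx(0.5)

    def test_hand_case_eight_ninths(self):
        # pairs won: 0.9 beats 3 negatives, 0.8 beats 3, 0.4 beats 2 -> 8/9
        r = binary_metrics([0.9, 0.8, 0.4, 0.7, 0.3, 0.2], [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(8 / 9, abs=1e-4)

    def test_auc_equals_pair_counting_up_to_n50(self):
        rng = np.random.default_rng(10)
        for n in (8, 20, 50):
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), 2)  # force some ties
            wins = ties = 0
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            for p, q in itertools.product(pos, neg):
                wins += p > q
                ties += p == q
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            got = binary_metrics(scores, labels).auc
            assert got == pytest.approx(expected, abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_nan_on_zero_denominator(self):
        with pytest.warns(UserWarning, match="PPV"):
            r = binary_metrics([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1],
                               threshold=0.9)
        assert np.isnan(r.ppv)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([0.1, 0.9], [1, 1])


class _MeanModel:
    """Trivial estimator: score = mean-profile distance to class means."""

    def fit(self, X, y):
        self.mu1 = X[y == 1].mean(axis=0)
        self.mu0 = X[y == 0].mean(axis=0)
        return self

    def predict_proba(self, X):
        d1 = np.linalg.norm(X - self.mu1, axis=1)
        d0 = np.linalg.norm(X - self.mu0, axis=1)
        p1 = d0 / (d0 + d1 + 1e-12)
        return np.column_stack([1 - p1, p1])


class TestCrossValidate:
    def _data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 5)) + y[:, None] * 0.8
        return X, y

    def test_default_protocol_yields_100_aucs(self):
        X, y = self._data(n=200)
        aucs, report = cross_validate(_MeanModel, X, y, n_repeats=10,
                                      n_folds=10, seed=1)
        assert len(aucs) == 100
        assert report.n_cv_values == 100
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]

    def test_stratified_folds_balanced(self):
        X, y = self._data(n=50)
        seen = []

        class Probe(_MeanModel):
            def fit(self, Xf, yf):
                seen.append(np.bincount(yf, minlength=2))
                return super().fit(Xf, yf)

        cross_validate(Probe, X, y, n_repeats=1, n_folds=5, seed=0)
        for counts in seen:  # each training fold drops 5 of each class
            assert tuple(counts) == (20, 20)

    def test_percentile_ci_interpolation_rule(self):
        values = np.arange(1, 101) / 100.0
        lo, hi = percentile_ci(values)
        assert lo == pytest.approx(0.03475)
        assert hi == pytest.approx(0.97525)

    def test_augment_applied_to_training_only(self):
        X, y = self._data(n=40)
        val_sizes = []

        class Probe(_MeanModel):
            def predict_proba(self, Xv):
                val_sizes.append(len(Xv))
                return super().predict_proba(Xv)

        def augment(X_tr, y_tr, fold_seed):
            return np.vstack([X_tr, X_tr]), np.concatenate([y_tr, y_tr])

        cross_validate(Probe, X, y, n_repeats=1, n_folds=4, seed=0,
                       augment=augment)
        assert all(v == 10 for v in val_sizes)  # validation folds unaugmented

    def test_too_few_samples_rejected(self):
        X, y = self._data(n=10)
        with pytest.raises(ValueError):
            cross_validate(_MeanModel, X, y, n_repeats=1, n_folds=10, seed=0)


class TestTrainTestSplit:
    def test_stratified_70_30(self):
        y = np.repeat([0, 1], 50)
        X = np.arange(100)[:, None].astype(float)
        X_tr, X_te, y_tr, y_te = train_test_split(X, y, 0.3, seed=4)
        assert len(y_tr) == 70 and len(y_te) == 30
        assert y_tr.sum() == 35 and y_te.sum() == 15

    def test_same_seed_same_split(self):
        y = np.repeat([0, 1], 20)
        X = np.arange(40)[:, None].astype(float)
        a = train_test_split(X, y, 0.3, seed=9)
        b = train_test_split(X, y, 0.3, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_union_is_original_multiset(self):
        y = np.repeat([0, 1], 20)
        X = np.arange(40)[:, None].astype(float)
        X_tr, X_te, _, _ = train_test_split(X, y, 0.25, seed=2)
        combined = sorted(np.concatenate([X_tr, X_te]).ravel().tolist())
        assert combined == list(range(40))
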