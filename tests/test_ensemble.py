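"""Single-source classifiers, stacking, feature selection and weight
reliability."""

import numpy as np
import pytest

from parcelstack.ensemble import (
    SingleSourceClassifier,
    StackedEnsembleClassifier,
    fit_pca_basis,
    reliability_scores,
    select_top_r,
    top_percentile_features,
)


def two_class_data(rng, n=60, p=10, informative=True):
    y = np.array([0, 1] * (n // 2))
    x = rng.standard_normal((n, p))
    if informative:
        x[:, 0] += 2.0 * y
    return x, y


class TestPcaBasis:
    def test_all_components_kept(self, rng):
        x = rng.standard_normal((30, 7))
        center, rotation = fit_pca_basis(x)
        assert rotation.shape == (7, 7)  # m = min(p, n) = 7
        np.testing.assert_allclose(rotation.T @ rotation, np.eye(7),
                                   atol=1e-8)

    def test_wide_matrix_keeps_n_components(self, rng):
        x = rng.standard_normal((10, 50))
        _, rotation = fit_pca_basis(x)
        assert rotation.shape == (50, 10)  # m = min(p, n) = 10

    def test_pairwise_distances_preserved(self, rng):
        x = rng.standard_normal((20, 12))
        center, rotation = fit_pca_basis(x)
        z = (x - center) @ rotation
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(z), pdist(x), atol=1e-8)

    def test_duplicate_rows_tolerated(self):
        x = np.tile([[1.0, 2.0, 3.0]], (6, 1))
        _, rotation = fit_pca_basis(x)
        np.testing.assert_allclose(rotation.T @ rotation, np.eye(3),
                                   atol=1e-8)


class TestSingleSource:
    def test_separable_data_ties_break_to_smallest_c(self):
        x = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 0.0], [5.1, 0.0]] * 6)
        y = np.array([0, 0, 1, 1] * 6)
        m = SingleSourceClassifier(inner_folds=3, inner_repeats=1,
                                   random_state=0).fit(x, y)
        assert m.chosen_C_ == 0.001
        assert np.mean(m.predict(x) == y) == 1.0

    def test_permuted_labels_give_chance_inner_accuracy(self, rng):
        x, y = two_class_data(rng, n=100)
        y = rng.permutation(y)
        m = SingleSourceClassifier(inner_folds=5, inner_repeats=2,
                                   random_state=0).fit(x, y)
        best = max(m.inner_scores_.values())
        assert abs(best - 0.5) < 0.2

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            SingleSourceClassifier().fit(x, np.zeros(10))

    def test_probability_closed_form_for_hand_set_weights(self, rng):
        x, y = two_class_data(rng)
        m = SingleSourceClassifier(selection="none", C_grid=(1.0,),
                                   random_state=0).fit(x, y)
        lr = m.pipeline_.named_steps["lr"]
        w, b = lr.coef_.ravel(), lr.intercept_[0]
        row = rng.standard_normal(x.shape[1])
        want = 1.0 / (1.0 + np.exp(-(row @ w + b)))
        assert m.predict_proba_positive(row) == pytest.approx(want,
                                                              abs=1e-12)

    def test_probability_monotone_in_aligned_feature(self, rng):
        x, y = two_class_data(rng)
        m = SingleSourceClassifier(selection="none", C_grid=(1.0,),
                                   random_state=0).fit(x, y)
        base = np.zeros(x.shape[1])
        bumped = base.copy()
        bumped[0] += 1.0  # feature 0 is aligned with the positive class
        assert m.predict_proba_positive(bumped) > (
            m.predict_proba_positive(base)
        )

    def test_feature_length_mismatch_rejected(self, rng):
        x, y = two_class_data(rng)
        m = SingleSourceClassifier(C_grid=(1.0,)).fit(x, y)
        with pytest.raises(ValueError):
            m.predict_proba(np.zeros(x.shape[1] + 1))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pca_rotation_invariance_of_probabilities(self, seed):
        # full-component PCA + L2 LR equals the no-projection fit
        rng = np.random.default_rng(seed)
        x, y = two_class_data(rng, n=50, p=8)
        x_test = rng.standard_normal((20, 8))
        p_pca = SingleSourceClassifier(
            selection="pca", C_grid=(1.0,), random_state=0
        ).fit(x, y).predict_proba_positive(x_test)
        p_none = SingleSourceClassifier(
            selection="none", C_grid=(1.0,), random_state=0
        ).fit(x, y).predict_proba_positive(x_test)
        np.testing.assert_allclose(p_pca, p_none, atol=1e-6)

    def test_refit_with_same_seed_is_identical(self, rng):
        x, y = two_class_data(rng, n=80)
        m1 = SingleSourceClassifier(inner_folds=5, inner_repeats=2,
                                    random_state=7).fit(x, y)
        m2 = SingleSourceClassifier(inner_folds=5, inner_repeats=2,
                                    random_state=7).fit(x, y)
        assert m1.chosen_C_ == m2.chosen_C_
        np.testing.assert_array_equal(m1.lr_weights_, m2.lr_weights_)


class TestTopR:
    def test_ceiling_keeps_one_of_two_hundred_at_half_percent(self, rng):
        x = rng.standard_normal((40, 200))
        y = np.array([0, 1] * 20)
        assert len(select_top_r(x, y, 0.5)) == 1

    def test_r_100_is_identity(self, rng):
        x = rng.standard_normal((30, 17))
        y = np.array([0, 1] * 15)
        np.testing.assert_array_equal(select_top_r(x, y, 100),
                                      np.arange(17))

    def test_nonpositive_r_rejected(self, rng):
        with pytest.raises(ValueError):
            select_top_r(rng.standard_normal((10, 5)),
                         np.array([0, 1] * 5), 0)

    def test_planted_informative_column_ranked_first(self):
        # effect size 2 SD at n=100: found in >= 95 of 100 replicates
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((100, 50))
            y = np.array([0, 1] * 50)
            x[:, 17] += 2.0 * y
            hits += select_top_r(x, y, 2)[0] == 17
        assert hits >= 95


class TestStack:
    def test_column_equal_to_labels_gives_perfect_training_fit(self, rng):
        y = np.array([0, 1] * 20)
        xs = {
            ("alff", "a"): rng.standard_normal((40, 4)),
            ("corr", "a"): np.column_stack([y + 0.0, rng.random(40)]),
        }
        ens = StackedEnsembleClassifier(C_grid=(1000.0,),
                                        random_state=0).fit(xs, y)
        assert np.mean(ens.predict(xs) == y) == 1.0

    def test_uninformative_probabilities_predict_majority(self, rng):
        y = np.array([0] * 30 + [1] * 15)
        xs = {("alff", "a"): np.zeros((45, 3))}
        ens = StackedEnsembleClassifier(
            C_grid=(0.001,), inner_folds=3, inner_repeats=1, random_state=0
        ).fit(xs, y)
        assert np.all(ens.predict(xs) == 0)

    def test_complementary_sources_beat_either_alone(self):
        # two weak sources, each informative on a disjoint half
        rng = np.random.default_rng(5)
        n = 120
        y = np.array([0, 1] * (n // 2))
        half = np.arange(n) < n // 2
        x1 = rng.standard_normal((n, 2))
        x2 = rng.standard_normal((n, 2))
        x1[half, 0] += 3.0 * y[half]
        x2[~half, 0] += 3.0 * y[~half]
        xs = {("alff", "a"): x1, ("corr", "a"): x2}
        ens = StackedEnsembleClassifier(inner_folds=5, inner_repeats=1,
                                        random_state=0).fit(xs, y)
        stack_acc = np.mean(ens.predict(xs) == y)
        base = ens.base_probabilities(xs)
        member_accs = [np.mean((base[:, j] >= 0.5) == y)
                       for j in range(base.shape[1])]
        assert stack_acc > max(member_accs)

    def test_source_count_asserted(self, rng):
        y = np.array([0, 1] * 10)
        xs = {("alff", "a"): rng.standard_normal((20, 3))}
        ens = StackedEnsembleClassifier(C_grid=(1.0,)).fit(xs, y)
        assert len(ens.base_models_) == 1
        with pytest.raises(ValueError, match="missing"):
            ens.base_probabilities({("reho", "a"): np.zeros((20, 3))})

    def test_per_type_substack_uses_member_subset(self, rng):
        y = np.array([0, 1] * 15)
        xs = {
            ("alff", "a"): rng.standard_normal((30, 3)),
            ("alff", "b"): rng.standard_normal((30, 3)),
            ("corr", "a"): rng.standard_normal((30, 3)),
        }
        ens = StackedEnsembleClassifier(C_grid=(1.0,),
                                        random_state=0).fit(xs, y)
        sub = ens.fit_substack("alff", [("alff", "a"), ("alff", "b")], y)
        assert sub.n_features_in_ == 2
        p = ens.predict_proba_positive(xs, substack="alff")
        assert p.shape == (30,)


class TestReliability:
    def test_hand_formula(self, rng):
        w = rng.normal(2.0, 0.1, size=(50, 3))
        scores, flagged = reliability_scores(w)
        expected = w.mean(0) / (w.std(0, ddof=1) / np.sqrt(50))
        np.testing.assert_allclose(scores, expected)
        assert not flagged.any()

    def test_zero_weight_across_folds_flagged_nan(self):
        w = np.zeros((4, 2))
        w[:, 1] = [1.0, 2.0, 3.0, 4.0]
        scores, flagged = reliability_scores(w)
        assert np.isnan(scores[0]) and flagged[0]
        assert np.isfinite(scores[1]) and not flagged[1]

    def test_constant_nonzero_weight_gives_signed_infinity(self):
        w = np.column_stack([np.ones(4), -np.ones(4)])
        scores, flagged = reliability_scores(w)
        assert scores[0] == np.inf and scores[1] == -np.inf
        assert flagged.all()

    def test_top_percentile_selects_extremes(self, rng):
        scores = rng.standard_normal(200)
        scores[7] = 50.0
        top = top_percentile_features(scores, 99)
        assert 7 in top
        assert len(top) <= 4
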