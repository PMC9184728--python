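"""Feature matrices, SMOTE, logistic / elastic-net models, splits."""

import numpy as np
import pandas as pd
import pytest

from dicpipe import mlfeat, synthio


def mk_sites(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"s{i}" for i in range(len(df))]
    return df


class TestFeatureMatrix:
    sites = mk_sites([("chr1", 0, 100), ("chr1", 200, 300),
                      ("chr1", 400, 500), ("chr2", 0, 100),
                      ("chr2", 200, 300)])

    def test_identical_dataset_all_ones(self):
        X = mlfeat.build_feature_matrix(self.sites, {"self": self.sites}, {})
        assert (X["self"] == 1).all()

    def test_disjoint_dataset_all_zeros(self):
        other = mk_sites([("chr3", 0, 100)])
        X = mlfeat.build_feature_matrix(self.sites, {"other": other}, {})
        assert (X["other"] == 0).all()

    def test_hand_overlap_table(self):
        ds = mk_sites([("chr1", 50, 250), ("chr2", 250, 260)])
        X = mlfeat.build_feature_matrix(self.sites, {"ds": ds}, {})
        assert list(X["ds"]) == [1.0, 1.0, 0.0, 0.0, 1.0]

    def test_continuous_z_scored(self):
        vals = np.array([1.0, 2, 3, 4, 5])
        X = mlfeat.build_feature_matrix(self.sites, {}, {"c": vals})
        assert X["c"].mean() == pytest.approx(0.0, abs=1e-12)
        assert X["c"].std(ddof=0) == pytest.approx(1.0)

    def test_zero_variance_track_dropped(self):
        with pytest.warns(UserWarning, match="zero variance"):
            X = mlfeat.build_feature_matrix(self.sites, {},
                                            {"flat": np.ones(5)})
        assert "flat" not in X.columns


class TestKMeans:
    def test_k1_single_cluster(self):
        X, _, _ = synthio.simulate_feature_matrix(n_sites=50, seed=0)
        assign, means = mlfeat.kmeans_cluster(X, k=1, seed=0)
        assert set(assign) == {0} and len(means) == 1

    def test_duplicated_rows_same_cluster(self):
        base = pd.DataFrame({"chrom": ["chr1"] * 6,
                             "f0": [0.0, 0, 0, 5, 5, 5],
                             "f1": [1.0, 1, 1, -4, -4, -4]})
        assign, _ = mlfeat.kmeans_cluster(base, k=2, seed=0)
        assert assign[0] == assign[1] == assign[2]
        assert assign[3] == assign[4] == assign[5]

    def test_invalid_k(self):
        X, _, _ = synthio.simulate_feature_matrix(n_sites=20, seed=0)
        with pytest.raises(ValueError):
            mlfeat.kmeans_cluster(X, k=0)


class TestSplit:
    def test_partitions_disjoint_and_balanced(self):
        X, _, _ = synthio.simulate_feature_matrix(n_sites=500, seed=2)
        split = mlfeat.make_split(X, ["chr16", "chr17"], folds=5, seed=0)
        fold = split.fold_assignment
        assert (fold[split.test_index] == -1).all()
        sizes = [int((fold == f).sum()) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1
        assert (fold >= 0).sum() + len(split.test_index) == len(X)

    def test_same_seed_identical(self):
        X, _, _ = synthio.simulate_feature_matrix(n_sites=200, seed=2)
        s1 = mlfeat.make_split(X, ["chr16"], seed=9)
        s2 = mlfeat.make_split(X, ["chr16"], seed=9)
        assert (s1.fold_assignment == s2.fold_assignment).all()

    def test_empty_test_set_rejected(self):
        X, _, _ = synthio.simulate_feature_matrix(n_sites=100, seed=2)
        with pytest.raises(ValueError):
            mlfeat.make_split(X, ["chrZ"])

    def test_everything_on_test_chroms_rejected(self):
        X, _, _ = synthio.simulate_feature_matrix(n_sites=100, n_chroms=1,
                                                  seed=2)
        with pytest.raises(ValueError):
            mlfeat.make_split(X, ["chr1"])


class TestSmote:
    def test_exact_balance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        y = np.r_[np.ones(10, int), np.zeros(50, int)]
        Xb, yb = mlfeat.smote_oversample(X, y, seed=1)
        assert (yb == 1).sum() == (yb == 0).sum() == 50

    def test_two_point_collinearity(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0]] + [[5.0, 5.0]] * 10)
        y = np.r_[1, 1, np.zeros(10, int)]
        Xb, yb = mlfeat.smote_oversample(X, y, k_neighbors=1, seed=3)
        synth = Xb[12:]
        # every synthetic point lies on the segment between the two minority points
        t = synth[:, 0] / 1.0
        np.testing.assert_allclose(synth[:, 1], 2.0 * t, atol=1e-12)
        assert ((t >= 0) & (t <= 1)).all()

    def test_synthetic_bounded_by_minority_range(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 5))
        y = (rng.random(80) < 0.2).astype(int)
        Xm = X[y == 1]
        Xb, yb = mlfeat.smote_oversample(X, y, seed=2)
        synth = Xb[len(X):]
        assert (synth >= Xm.min(axis=0) - 1e-12).all()
        assert (synth <= Xm.max(axis=0) + 1e-12).all()

    def test_binary_columns_rounded(self):
        rng = np.random.default_rng(1)
        X = np.c_[(rng.random(40) < 0.5).astype(float), rng.normal(size=40)]
        y = np.r_[np.ones(8, int), np.zeros(32, int)]
        Xb, _ = mlfeat.smote_oversample(X, y, seed=1, binary_columns=[0])
        assert set(np.unique(Xb[:, 0])) <= {0.0, 1.0}

    def test_tiny_minority_rejected(self):
        with pytest.raises(ValueError):
            mlfeat.smote_oversample(np.zeros((5, 2)),
                                    np.array([1, 0, 0, 0, 0]))


class TestLogistic:
    def test_zero_coefficients_give_half(self):
        m = mlfeat.LogisticModel(0.0, np.zeros(3), ["a", "b", "c"])
        np.testing.assert_allclose(m.predict_proba(np.ones((4, 3))), 0.5)

    def test_intercept_ln3_gives_three_quarters(self):
        m = mlfeat.LogisticModel(np.log(3.0), np.zeros(1), ["a"])
        assert m.predict_proba(np.zeros((1, 1)))[0] == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mlfeat.train_logistic(np.zeros((5, 2)), np.ones(5))

    def test_affine_rescaling_invariance(self):
        """Rescaling a feature and its coefficient leaves predictions fixed."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        m = mlfeat.LogisticModel(0.3, np.array([1.0, -2.0, 0.5]), list("abc"))
        scaled = X.copy()
        scaled[:, 1] *= 10
        m2 = mlfeat.LogisticModel(0.3, np.array([1.0, -0.2, 0.5]), list("abc"))
        np.testing.assert_allclose(m.predict_proba(X),
                                   m2.predict_proba(scaled))


class TestEvaluation:
    def test_perfect_separation(self):
        m = mlfeat.LogisticModel(0.0, np.array([10.0]), ["a"])
        X = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        out = mlfeat.evaluate_classifier(m, X, y)
        assert out["auroc"] == 1.0

    def test_constant_predictions_half(self):
        m = mlfeat.LogisticModel(0.0, np.zeros(1), ["a"])
        out = mlfeat.evaluate_classifier(m, np.zeros((6, 1)),
                                         np.array([0, 1, 0, 1, 0, 1]))
        assert out["auroc"] == 0.5

    def test_auroc_equals_rank_statistic(self):
        """AUROC identity with the scaled Mann–Whitney U on a hand fixture."""
        m = mlfeat.LogisticModel(0.0, np.array([1.0]), ["a"])
        X = np.array([[0.1], [0.4], [0.35], [0.8], [0.7], [0.2]])
        y = np.array([0, 0, 1, 1, 1, 0])
        out = mlfeat.evaluate_classifier(m, X, y)
        scores = m.predict_proba(X)
        pos, neg = scores[y == 1], scores[y == 0]
        u = (pos[:, None] > neg[None, :]).sum() \
            + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert out["auroc"] == pytest.approx(u / (3 * 3))

    def test_one_class_test_set_missing_auroc(self):
        m = mlfeat.LogisticModel(0.0, np.zeros(1), ["a"])
        out = mlfeat.evaluate_classifier(m, np.zeros((3, 1)), np.zeros(3))
        assert out["auroc"] is None


class TestImportance:
    def test_ranked_by_magnitude_with_sign(self):
        m = mlfeat.LogisticModel(0.0, np.array([0.5, -2.0, 1.0]),
                                 ["a", "b", "c"])
        imp = mlfeat.feature_importance(m)
        assert list(imp["feature"]) == ["b", "c", "a"]
        assert imp["importance"].iloc[0] == -2.0

    def test_duplicated_feature_warns(self):
        m = mlfeat.LogisticModel(0.0, np.array([1.0, 1.0]), ["a", "a"])
        with pytest.warns(UserWarning, match="duplicated"):
            mlfeat.feature_importance(m)


class TestElasticNet:
    def test_lambda_zero_matches_ols(self):
        X, y, _ = synthio.simulate_regression_matrix(n=200, p=20, k=3, seed=4)
        en = mlfeat.elastic_net_select(X, y, lam_grid=0.0)
        coef, *_ = np.linalg.lstsq(np.c_[np.ones(len(y)), X], y, rcond=None)
        np.testing.assert_allclose(en.coefficients, coef[1:], atol=1e-6)

    def test_huge_lambda_all_zero(self):
        X, y, _ = synthio.simulate_regression_matrix(n=200, p=20, k=3, seed=4)
        with pytest.warns(UserWarning, match="zero"):
            en = mlfeat.elastic_net_select(X, y, lam_grid=1e6)
        assert not en.survivors

    def test_subgradient_optimality(self):
        X, y, _ = synthio.simulate_regression_matrix(n=400, p=30, k=4, seed=6)
        en = mlfeat.elastic_net_select(X, y, seed=6)
        assert mlfeat.subgradient_residual(en, X, y) < 1e-6

    def test_univariate_slopes_sign_match(self):
        X, y, beta = synthio.simulate_regression_matrix(n=800, p=30, k=4,
                                                        snr=5.0, seed=7)
        en = mlfeat.elastic_net_select(X, y, seed=7)
        uni = mlfeat.univariate_coefficients(X, y, en)
        for row in uni.itertuples():
            j = int(row.feature[1:])
            if beta[j] != 0:
                assert np.sign(row.slope) == np.sign(beta[j])


class TestCrossPrediction:
    def test_self_consistency_enriched(self):
        X, y, _ = synthio.simulate_feature_matrix(n_sites=1500, seed=11)
        split = mlfeat.make_split(X, ["chr16", "chr17"], seed=11)
        model, _ = mlfeat.train_dic_classifier(X, y, split, seed=11)
        out = mlfeat.predict_cross(model, X.drop(columns=[]), y.astype(bool))
        assert out["p"] < 0.01

    def test_feature_mismatch_hard_error(self):
        X, y, _ = synthio.simulate_feature_matrix(n_sites=300, seed=11)
        split = mlfeat.make_split(X, ["chr16"], seed=11)
        model, _ = mlfeat.train_dic_classifier(X, y, split, seed=11)
        with pytest.raises(ValueError, match="match"):
            mlfeat.predict_cross(model, X.iloc[:, :-2], y.astype(bool))

    def test_permuted_labels_null(self):
        X, y, _ = synthio.simulate_feature_matrix(n_sites=800, seed=13)
        split = mlfeat.make_split(X, ["chr16", "chr17"], seed=13)
        model, _ = mlfeat.train_dic_classifier(X, y, split, seed=13)
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(20):
            perm = rng.permutation(y).astype(bool)
            ps.append(mlfeat.predict_cross(model, X, perm)["p"])
        assert np.median(ps) > 0.1
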