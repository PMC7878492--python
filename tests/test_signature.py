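"""Signature-building tests: penalized path properties against independent
optimizers, CV and stability-selection behavior, integrated-model refit, and
ROC/AUC against combinatorial and sklearn oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hmcseal import diffmod, signature, synthetic
from hmcseal.signature import (
    PenalizedLogisticSpec,
    SignatureModel,
    cv_select_lambda,
    fit_integrated_model,
    fit_penalized_logistic,
    roc_auc,
    split_train_test,
    stability_selection,
)


def _logistic_data(rng, n=80, p=5, beta=None):
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
    eta = X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if y.min() == y.max():  # ensure both classes
        y[0] = 1 - y[0]
    return X, y


class TestSplit:
    def test_published_cohort_sizes(self):
        cohort = synthetic.generate_cohort(48, 25, seed=1)
        train, test = split_train_test(cohort, seed=2)
        sub = cohort.set_index("sample_id")["subtype"]
        assert (sub.loc[train] == "DLBCL").sum() == 24
        assert (sub.loc[train] == "FL").sum() == 13
        assert (sub.loc[test] == "DLBCL").sum() == 24
        assert (sub.loc[test] == "FL").sum() == 12

    def test_deterministic(self):
        cohort = synthetic.generate_cohort(20, 10, seed=3)
        assert split_train_test(cohort, seed=9) == split_train_test(cohort, seed=9)

    def test_age_balance_over_cohorts(self):
        # pair-matching keeps train/test age means within half a pooled SD
        rng = np.random.default_rng(4)
        ok = 0
        n_rep = 200
        for rep in range(n_rep):
            cohort = synthetic.generate_cohort(24, 12, seed=int(rng.integers(1e6)))
            train, test = split_train_test(cohort, seed=int(rng.integers(1e6)))
            age = cohort.set_index("sample_id")["age"]
            sd = age.std()
            if abs(age.loc[train].mean() - age.loc[test].mean()) < 0.5 * sd:
                ok += 1
        assert ok / n_rep >= 0.95


class TestPenalizedPath:
    def test_huge_lambda_zeroes_penalized_coefficients(self):
        rng = np.random.default_rng(11)
        X, y = _logistic_data(rng, beta=np.array([2.0, 0, 0, 0, 0]))
        spec = PenalizedLogisticSpec(alpha=0.5,
                                     lambda_grid=np.array([1e4]))
        path = fit_penalized_logistic(X, y, spec)
        np.testing.assert_allclose(path["coefs"][0], 0.0)

    def test_ridge_matches_independent_optimizer(self):
        rng = np.random.default_rng(12)
        X, y = _logistic_data(rng, n=100, p=2,
                              beta=np.array([1.0, -0.5]))
        lam = 0.1
        spec = PenalizedLogisticSpec(alpha=0.0, lambda_grid=np.array([lam]),
                                     standardize=False)
        path = fit_penalized_logistic(X, y, spec)
        mine = np.r_[path["intercepts"][0], path["coefs"][0]]
        Xc = X - X.mean(axis=0)

        def obj(w):
            eta = w[0] + Xc @ w[1:]
            return (-np.mean(y * eta - np.log1p(np.exp(eta)))
                    + lam * 0.5 * np.sum(w[1:] ** 2))

        res = minimize(obj, np.zeros(3), method="BFGS")
        oracle = np.r_[res.x[0] - res.x[1:] @ X.mean(axis=0), res.x[1:]]
        np.testing.assert_allclose(mine, oracle, atol=1e-4)

    def test_lasso_matches_independent_optimizer(self):
        # subgradient-smoothed oracle via sklearn's saga solver
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(13)
        X, y = _logistic_data(rng, n=120, p=6,
                              beta=np.array([1.5, -1.0, 0, 0, 0, 0]))
        lam = 0.05
        spec = PenalizedLogisticSpec(alpha=1.0, lambda_grid=np.array([lam]),
                                     standardize=False)
        path = fit_penalized_logistic(X, y, spec)
        # sklearn: minimizes (1/C) * ||b||_1 + sum loglik; C = 1/(n*lam)
        ref = LogisticRegression(penalty="l1", C=1.0 / (len(y) * lam),
                                 solver="saga", tol=1e-10, max_iter=50_000)
        ref.fit(X, y)
        np.testing.assert_allclose(path["coefs"][0], ref.coef_[0], atol=2e-3)

    def test_unpenalized_covariates_survive_large_lambda(self):
        rng = np.random.default_rng(14)
        X, y = _logistic_data(rng, n=150, p=4,
                              beta=np.array([0.0, 0.0, 1.5, 1.0]))
        v = np.array([1.0, 1.0, 0.0, 0.0])
        spec = PenalizedLogisticSpec(alpha=0.5, lambda_grid=np.array([10.0]),
                                     penalty_factors=v)
        path = fit_penalized_logistic(X, y, spec)
        assert np.allclose(path["coefs"][0, :2], 0.0)
        assert (np.abs(path["coefs"][0, 2:]) > 0.1).all()

    def test_lasso_support_monotone_on_path(self):
        rng = np.random.default_rng(15)
        X, y = _logistic_data(rng, n=60, p=8,
                              beta=np.array([2, -1.5, 1, 0, 0, 0, 0, 0.0]))
        spec = PenalizedLogisticSpec(alpha=1.0, n_lambda=40)
        path = fit_penalized_logistic(X, y, spec)
        nnz = (path["coefs"] != 0).sum(axis=1)
        # non-decreasing active set as lambda decreases (small instances)
        assert (np.diff(nnz) >= 0).all()

    def test_single_class_rejected(self):
        X = np.random.default_rng(16).normal(size=(10, 2))
        with pytest.raises(ValueError, match="two classes"):
            fit_penalized_logistic(X, np.ones(10), PenalizedLogisticSpec())

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(17)
        X, y = _logistic_data(rng, n=40, p=3)
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            path = fit_penalized_logistic(X, y, PenalizedLogisticSpec(
                lambda_grid=np.array([0.01])))
        assert path["coefs"][0, 1] == 0.0


class TestCV:
    def test_pure_noise_prefers_sparse_end(self):
        rng = np.random.default_rng(21)
        hits = 0
        for rep in range(10):
            X, y = _logistic_data(rng, n=60, p=10)
            spec = PenalizedLogisticSpec(alpha=0.5, n_lambda=30)
            lam, grid, dev = cv_select_lambda(X, y, spec,
                                              seed=int(rng.integers(1e6)))
            if lam >= np.median(grid):
                hits += 1
        assert hits >= 7

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(22)
        X, y = _logistic_data(rng, n=50, p=4, beta=np.array([1.5, 0, 0, 0]))
        spec = PenalizedLogisticSpec(alpha=0.5, n_lambda=25)
        a = cv_select_lambda(X, y, spec, seed=5)
        b = cv_select_lambda(X, y, spec, seed=5)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[2], b[2])


class TestStabilitySelection:
    def test_dominant_feature_always_selected(self):
        rng = np.random.default_rng(31)
        n = 60
        X = rng.normal(size=(n, 6))
        y = (X[:, 0] + 0.1 * rng.normal(size=n) > 0).astype(float)
        Xdf = pd.DataFrame(X, columns=[f"g{i}" for i in range(6)])
        spec = PenalizedLogisticSpec(alpha=0.5, n_lambda=30, n_folds=5)
        selected, freq = stability_selection(Xdf, y, spec, repeats=20,
                                             threshold=0.9, seed=32)
        assert "g0" in selected
        assert freq["g0"] == 1.0

    def test_planted_recovery_among_candidates(self):
        # 4 group-shifted genes (effect ~2 within-group SDs, like strong
        # 5hmc-level differences) among ~300 candidate features
        rng = np.random.default_rng(33)
        n, p = 73, 300
        y = np.r_[np.zeros(48), np.ones(25)]
        X = rng.normal(size=(n, p))
        X[:, :4] += np.outer(2 * y - 1, np.full(4, 1.0))
        Xdf = pd.DataFrame(X, columns=[f"g{i}" for i in range(p)])
        spec = PenalizedLogisticSpec(alpha=0.5, n_lambda=50)
        selected, freq = stability_selection(Xdf, y, spec, repeats=25,
                                             threshold=0.9, seed=34)
        assert set(f"g{i}" for i in range(4)) <= set(selected)
        assert len(selected) <= 6

    def test_noise_frequency_low(self):
        # one moderately informative gene among pure noise: noise features
        # should be selected only sporadically
        rng = np.random.default_rng(35)
        n, p = 60, 150
        y = np.r_[np.zeros(30), np.ones(30)]
        X = rng.normal(size=(n, p))
        X[:, 0] += (2 * y - 1) * 0.9
        Xdf = pd.DataFrame(X, columns=[f"g{i}" for i in range(p)])
        spec = PenalizedLogisticSpec(alpha=0.5, n_lambda=30, n_folds=5)
        _, freq = stability_selection(Xdf, y, spec, repeats=20, threshold=0.9,
                                      seed=36)
        assert freq["g0"] == 1.0
        assert freq.drop("g0").mean() < 0.2


@pytest.fixture(scope="module")
def fitted():
    cohort = synthetic.generate_cohort(24, 16, seed=41)
    ann = synthetic.generate_annotation(80, 2, 6_000_000, seed=42)
    counts, truth = synthetic.generate_counts(
        cohort, ann, n_planted=3, log2fc=2.0, dispersion=0.05,
        libsize_cv=0.2, seed=43)
    counts = diffmod.filter_nonzero_variance(counts)
    sf = diffmod.size_factors(counts)
    levels = diffmod.normalized_log2(counts, sf).T
    genes = truth.planted_genes
    model = fit_integrated_model(levels[genes], genes, cohort, seed=44)
    return cohort, levels, genes, model


class TestIntegratedModel:
    def test_refit_deterministic(self, fitted):
        cohort, levels, genes, model = fitted
        again = fit_integrated_model(levels[genes], genes, cohort, seed=44)
        np.testing.assert_array_equal(model.coefficients, again.coefficients)

    def test_strong_signal_training_auc_near_one(self, fitted):
        cohort, levels, genes, model = fitted
        feats = levels[genes].copy()
        clin = cohort.set_index("sample_id")
        feats["age"] = clin.loc[feats.index, "age"]
        feats["gender_M"] = (clin.loc[feats.index, "gender"] == "M").astype(float)
        y = (clin.loc[feats.index, "subtype"] == "FL").astype(int)
        roc = roc_auc(model.score(feats), y.to_numpy())
        assert roc.auc > 0.95

    def test_feature_vector_shape_enforced(self):
        with pytest.raises(ValueError):
            SignatureModel(features=["a", "b"], intercept=0.0,
                           coefficients=np.array([1.0]),
                           feature_means=np.zeros(1), feature_sds=np.ones(1))

    def test_json_round_trip(self, fitted, tmp_path):
        *_, model = fitted
        p = tmp_path / "model.json"
        model.to_json(p)
        back = SignatureModel.from_json(p)
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.features == model.features

    def test_empty_gene_list_rejected(self, fitted):
        cohort, levels, genes, _ = fitted
        with pytest.raises(ValueError):
            fit_integrated_model(levels[genes], [], cohort)


class TestROC:
    def test_perfect_scores(self):
        r = roc_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(51)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        r = roc_auc(scores, labels)
        assert abs(r.auc - 0.5) < 0.05
        assert r.ci_low < 0.5 < r.ci_high

    def test_matches_concordant_pair_oracle(self):
        rng = np.random.default_rng(52)
        for _ in range(20):
            scores = rng.integers(0, 8, size=20).astype(float)  # force ties
            labels = rng.integers(0, 2, size=20)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = conc / (len(pos) * len(neg))
            assert roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(53)
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 1 / (1 + np.exp(-scores))).astype(int)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores))

    def test_complement_symmetry(self):
        rng = np.random.default_rng(54)
        scores = rng.normal(size=100)  # tie-free
        labels = rng.integers(0, 2, size=100)
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(55)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b)

    def test_bootstrap_ci_contains_auc(self):
        rng = np.random.default_rng(56)
        scores = rng.normal(size=60) + rng.integers(0, 2, size=60)
        labels = (scores > 0.5).astype(int)
        labels[::7] = 1 - labels[::7]
        r = roc_auc(scores, labels, ci_method="bootstrap", n_boot=500, seed=1)
        assert r.ci_low <= r.auc <= r.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
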