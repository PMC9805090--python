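import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from msewas.classify import (
    compute_wmrs,
    elastic_net_objective,
    fit_elastic_net,
    roc_auc,
    split_cohort,
    tune_elastic_net,
    variable_importance,
    wmrs_model,
)


def brute_force_auc(scores, labels):
    """All-pairs concordance count: (wins + 0.5 ties) / (n1 * n0)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSplitCohort:
    def test_study_sized_cohort_splits_164_71(self):
        ids = [f"s{i}" for i in range(235)]
        labels = pd.Series(["mild"] * 119 + ["severe"] * 116, index=ids)
        train, test = split_cohort(ids, labels, seed=0)
        assert len(train) == 164 and len(test) == 71
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(ids)

    def test_balanced_ten_splits_seven_three(self):
        ids = list("abcdefghij")
        labels = pd.Series(["x"] * 5 + ["y"] * 5, index=ids)
        train, test = split_cohort(ids, labels, seed=1)
        assert len(train) == 7 and len(test) == 3

    def test_stratification_preserved(self):
        ids = [f"s{i}" for i in range(100)]
        labels = pd.Series(["mild"] * 50 + ["severe"] * 50, index=ids)
        train, _ = split_cohort(ids, labels, seed=2)
        lab_train = labels.loc[train]
        assert abs((lab_train == "mild").sum() - 35) <= 1

    def test_same_seed_identical_split(self):
        ids = [f"s{i}" for i in range(30)]
        labels = pd.Series(["a"] * 15 + ["b"] * 15, index=ids)
        assert split_cohort(ids, labels, seed=9) == split_cohort(ids, labels, seed=9)

    def test_tiny_stratum_rejected(self):
        labels = pd.Series(["a", "b", "b", "b"], index=list("wxyz"))
        with pytest.raises(ValueError):
            split_cohort(list("wxyz"), labels)


@pytest.fixture()
def toy_logistic_data(rng):
    n = 120
    X = pd.DataFrame(
        {
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(0, 1, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    eta = 1.2 * X["x1"] - 0.5 * X["x2"] + 0.3
    y = pd.Series(
        (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int), index=X.index
    )
    if y.nunique() < 2:
        y.iloc[0] = 1 - y.iloc[0]
    return X, y


class TestFitElasticNet:
    def test_lambda_zero_matches_unpenalised_logistic(self, toy_logistic_data):
        X, y = toy_logistic_data
        model = fit_elastic_net(X, y, alpha=0.5, lambda_=0.0)
        ref = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy())).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-4)
        assert model.coefficients["x1"] == pytest.approx(ref.params[1], abs=1e-4)
        assert model.coefficients["x2"] == pytest.approx(ref.params[2], abs=1e-4)

    def test_huge_lambda_null_model_with_prevalence_intercept(self, toy_logistic_data):
        X, y = toy_logistic_data
        model = fit_elastic_net(X, y, alpha=0.5, lambda_=100.0)
        assert (model.coefficients == 0).all()
        prevalence = y.mean()
        assert model.intercept == pytest.approx(
            np.log(prevalence / (1 - prevalence)), abs=0.05
        )

    def test_lasso_on_duplicate_features_shares_one_coefficient(self, toy_logistic_data):
        # the L1 solution over exact duplicates is non-unique in how the
        # weight is split, but the total weight (hence the predictor)
        # matches the fit without the duplicate
        X, y = toy_logistic_data
        Xd = X.copy()
        Xd["x1_dup"] = Xd["x1"]
        plain = fit_elastic_net(X, y, alpha=1.0, lambda_=0.05)
        dup = fit_elastic_net(Xd, y, alpha=1.0, lambda_=0.05)
        combined = dup.coefficients["x1"] + dup.coefficients["x1_dup"]
        assert combined == pytest.approx(plain.coefficients["x1"], abs=1e-3)
        assert np.sign(dup.coefficients["x1"]) != -np.sign(dup.coefficients["x1_dup"])

    def test_fitted_solution_minimises_penalised_objective(self, toy_logistic_data):
        # no small perturbation of the coefficients may improve the
        # objective the solver minimises
        X, y = toy_logistic_data
        model = fit_elastic_net(X, y, alpha=0.3, lambda_=0.02)
        base = elastic_net_objective(model, X, y)
        rng = np.random.default_rng(5)
        for _ in range(30):
            bumped = model.__class__(
                alpha=model.alpha,
                lambda_=model.lambda_,
                coefficients=model.coefficients * 1.0,
                coefficients_std=model.coefficients_std
                + rng.normal(0, 0.02, len(model.coefficients_std)),
                intercept=model.intercept,
                feature_means=model.feature_means,
                feature_sds=model.feature_sds,
            )
            assert elastic_net_objective(bumped, X, y) >= base - 1e-6

    def test_constant_labels_rejected(self, toy_logistic_data):
        X, _ = toy_logistic_data
        with pytest.raises(ValueError):
            fit_elastic_net(X, pd.Series(1, index=X.index), 0.5, 0.1)


class TestTuneElasticNet:
    def test_pure_noise_prefers_heavy_penalty(self, rng):
        n = 80
        X = pd.DataFrame(
            rng.normal(0, 1, (n, 20)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"f{j}" for j in range(20)],
        )
        y = pd.Series(([0, 1] * (n // 2)), index=X.index)
        alpha, lam = tune_elastic_net(X, y, alpha_grid=(0.5,), k_folds=4, seed=0)
        model = fit_elastic_net(X, y, alpha, lam)
        assert len(model.selected_features) <= 3

    def test_perfect_feature_selected(self, rng):
        n = 80
        y = pd.Series([0] * 40 + [1] * 40, index=[f"s{i}" for i in range(n)])
        X = pd.DataFrame(
            rng.normal(0, 1, (n, 10)),
            index=y.index,
            columns=[f"f{j}" for j in range(10)],
        )
        X["signal"] = y * 2.0 + rng.normal(0, 0.3, n)
        alpha, lam = tune_elastic_net(X, y, alpha_grid=(1.0,), k_folds=4, seed=0)
        model = fit_elastic_net(X, y, alpha, lam)
        assert "signal" in model.selected_features

    def test_single_alpha_grid_reduces_to_lambda_cv(self, rng):
        X = pd.DataFrame(
            rng.normal(0, 1, (40, 5)), index=[f"s{i}" for i in range(40)]
        )
        y = pd.Series([0, 1] * 20, index=X.index)
        alpha, lam = tune_elastic_net(X, y, alpha_grid=(0.7,), k_folds=4, seed=1)
        assert alpha == 0.7 and lam > 0

    def test_excessive_folds_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (10, 2)), index=[f"s{i}" for i in range(10)])
        y = pd.Series([0] * 5 + [1] * 5, index=X.index)
        with pytest.raises(ValueError, match="k_folds"):
            tune_elastic_net(X, y, k_folds=8)


class TestVariableImportance:
    def test_single_nonzero_gets_100(self):
        model = _fake_model(coef_std={"a": 0.0, "b": -0.4})
        imp = variable_importance(model)
        assert imp["b"] == 100.0 and imp["a"] == 0.0

    def test_two_to_one_ratio(self):
        imp = variable_importance(_fake_model(coef_std={"a": 2.0, "b": 1.0}))
        assert imp["a"] == 100.0 and imp["b"] == 50.0

    def test_all_zero_model(self):
        imp = variable_importance(_fake_model(coef_std={"a": 0.0, "b": 0.0}))
        assert (imp == 0).all()


def _fake_model(coef_std):
    from msewas.classify import ElasticNetModel

    s = pd.Series(coef_std)
    return ElasticNetModel(
        alpha=0.5,
        lambda_=0.1,
        coefficients=s,
        coefficients_std=s,
        intercept=0.0,
        feature_means=s * 0,
        feature_sds=s * 0 + 1,
    )


class TestWmrs:
    def test_zero_weights_zero_score(self, rng):
        beta = pd.DataFrame(
            rng.uniform(0.2, 0.8, (3, 5)),
            index=["cg1", "cg2", "cg3"],
            columns=[f"s{i}" for i in range(5)],
        )
        weights = pd.Series(0.0, index=beta.index)
        scores = compute_wmrs(beta, weights, beta.mean(axis=1), beta.std(axis=1))
        assert np.allclose(scores, 0.0)

    def test_one_sd_above_mean_scores_weight(self):
        means = pd.Series({"cg1": 0.5})
        sds = pd.Series({"cg1": 0.1})
        beta = pd.DataFrame({"s1": [0.6]}, index=["cg1"])  # z = +1
        scores = compute_wmrs(beta, pd.Series({"cg1": 0.05}), means, sds)
        assert scores["s1"] == pytest.approx(0.05)

    def test_linearity_in_weights(self, rng):
        beta = pd.DataFrame(
            rng.uniform(0.2, 0.8, (4, 6)),
            index=[f"cg{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(6)],
        )
        w = pd.Series(rng.normal(0, 0.05, 4), index=beta.index)
        means, sds = beta.mean(axis=1), beta.std(axis=1)
        s1 = compute_wmrs(beta, w, means, sds)
        s3 = compute_wmrs(beta, 3 * w, means, sds)
        assert np.allclose(s3, 3 * s1)

    def test_zero_sd_dmp_dropped_with_warning(self, rng):
        beta = pd.DataFrame(
            {"s1": [0.5, 0.3], "s2": [0.5, 0.7]}, index=["flat", "ok"]
        )
        means = beta.mean(axis=1)
        sds = beta.std(axis=1)
        with pytest.warns(UserWarning, match="zero training SD"):
            scores = compute_wmrs(
                beta, pd.Series({"flat": 0.1, "ok": 0.05}), means, sds
            )
        assert np.isfinite(scores).all()

    def test_wmrs_separates_groups_on_planted_cohort(self, small_cohort):
        from msewas.dmp import filter_dmps
        from msewas.dmp import test_dmps as scan

        beta = small_cohort.beta.beta
        labels = small_cohort.group
        hits = filter_dmps(scan(beta, labels))
        weights = hits["delta_meth"]
        means = beta.loc[weights.index].mean(axis=1)
        sds = beta.loc[weights.index].std(axis=1)
        scores = compute_wmrs(beta, weights, means, sds)
        model = wmrs_model(scores, labels)
        assert model.p_value < 0.01 or model.flag == "separation"
        severe_mean = scores[labels == "severe"].mean()
        mild_mean = scores[labels == "mild"].mean()
        assert severe_mean > mild_mean


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        out = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert out.auc == pytest.approx(1.0)

    def test_interleaved_scores_auc_075(self):
        out = roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert out.auc == pytest.approx(0.75)

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.normal(0, 1, n), 1)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_random_scores_auc_near_half(self, rng):
        scores = rng.normal(0, 1, 4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.04)

    def test_curve_monotone(self, rng):
        scores = rng.normal(0, 1, 100)
        labels = rng.integers(0, 2, 100)
        out = roc_auc(scores, labels)
        assert (np.diff(out.sensitivities) >= -1e-12).all()
        assert (np.diff(out.specificities) <= 1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestLeakageGuard:
    def test_overlapping_split_rejected(self, small_cohort):
        from msewas.classify import compare_models

        labels = small_cohort.group
        ids = list(labels.index)
        clin = small_cohort.sample_sheet.set_index("sample_id")[["age_at_onset"]]
        meth = small_cohort.beta.beta.T
        with pytest.raises(ValueError, match="leakage"):
            compare_models(
                clin, meth, pd.Series(dtype=float), labels,
                (ids[:60], ids[50:]),
            )
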