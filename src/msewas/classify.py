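"""Severity classification: elastic-net models and the weighted
methylation risk score (wMRS).

Three models mirror the standard design for testing methylation as a
prognostic biomarker on a 70:30 train:test split:

* model 1 — elastic-net logistic regression on clinical features
  available at diagnosis (age at onset plus first-symptom indicators);
* model 2 — elastic-net logistic regression on genome-wide methylation
  (plus cell-proportion estimates when supplied);
* model 3 — a wMRS: for each discovery DMP i with group difference
  delta_beta_i, wMRS(s) = sum_i z_i(s) * delta_beta_i, where z_i is the
  beta value standardised with training-set mean/SD; the score feeds a
  univariate logistic model.

The elastic net uses the glmnet parametrisation: penalty
lambda * (alpha * |coef|_1 + (1 - alpha)/2 * |coef|_2^2) added to the
mean logistic deviance, with features standardised internally and
coefficients reported on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .dmp import _encode_labels, _ridge_logit


@dataclass
class ElasticNetModel:
    alpha: float
    lambda_: float
    coefficients: pd.Series  # original feature scale
    coefficients_std: pd.Series  # standardised-feature scale
    intercept: float
    feature_means: pd.Series
    feature_sds: pd.Series

    @property
    def selected_features(self) -> list[str]:
        return list(self.coefficients.index[self.coefficients != 0])

    @property
    def importance(self) -> pd.Series:
        return variable_importance(self)

    def decision_function(self, X: pd.DataFrame) -> pd.Series:
        return X[self.coefficients.index] @ self.coefficients + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> pd.Series:
        eta = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class WmrsModel:
    weights: pd.Series  # delta_beta per DMP
    train_means: pd.Series
    train_sds: pd.Series
    coefficient: float = np.nan
    intercept: float = np.nan
    p_value: float = np.nan
    flag: str = ""


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


def split_cohort(
    sample_ids, labels, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Stratified train/test split.

    The pooled training size is floor(train_fraction * n); it is
    allocated across label strata by largest remainder so that the split
    of a 235-sample 119/116 cohort at 0.7 is exactly 164/71 and a
    balanced 10-sample cohort splits 7/3. Deterministic given the seed;
    train and test are disjoint and exhaustive.
    """
    ids = pd.Index(sample_ids)
    lab = pd.Series(labels, index=ids) if not isinstance(labels, pd.Series) else labels.loc[ids]
    strata = lab.groupby(lab).groups
    if any(len(v) < 2 for v in strata.values()):
        raise ValueError("each stratum needs >= 2 samples")
    n_train_total = int(np.floor(train_fraction * len(ids)))
    quotas = {k: train_fraction * len(v) for k, v in strata.items()}
    base = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = n_train_total - sum(base.values())
    # distribute leftovers to largest fractional parts (ties: stratum order)
    order = sorted(strata, key=lambda k: -(quotas[k] - base[k]))
    for k in order[:remainder]:
        base[k] += 1
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for k, members in strata.items():
        members = list(members)
        perm = rng.permutation(len(members))
        chosen = [members[i] for i in perm[: base[k]]]
        train.extend(chosen)
        test.extend(m for m in members if m not in set(chosen))
    return train, test


def _standardize(X: pd.DataFrame) -> tuple[np.ndarray, pd.Series, pd.Series]:
    means = X.mean()
    sds = X.std(ddof=0)
    usable = sds > 0
    Z = ((X - means) / sds.where(usable, 1.0)).to_numpy(float)
    Z[:, ~usable.to_numpy()] = 0.0
    return Z, means, sds


def fit_elastic_net(
    X: pd.DataFrame, y, alpha: float, lambda_: float, tol: float = 1e-4
) -> ElasticNetModel:
    """Penalised logistic regression in the glmnet parametrisation.

    Features are standardised internally; the solver minimises the mean
    logistic deviance plus lambda * (alpha*L1 + (1-alpha)/2*L2) on the
    standardised scale, and coefficients are mapped back to the original
    scale. lambda_ = 0 gives the unpenalised logistic fit. Constant
    features get coefficient 0.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    yv = _encode_labels(pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y.loc[X.index])
    if len(np.unique(yv)) < 2:
        raise ValueError("labels are constant")
    Z, means, sds = _standardize(X)
    n = len(yv)
    if lambda_ == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
    else:
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            C=1.0 / (n * lambda_),
            max_iter=30000,
            tol=tol,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, yv)
    if clf.n_iter_[0] >= getattr(clf, "max_iter", np.inf):
        raise RuntimeError(
            f"elastic net failed to converge (alpha={alpha}, lambda={lambda_}, "
            f"{clf.n_iter_[0]} passes)"
        )
    coef_std = pd.Series(clf.coef_[0], index=X.columns)
    usable = sds > 0
    coef_orig = coef_std.where(usable, 0.0) / sds.where(usable, 1.0)
    if (coef_std == 0).all():
        # null model: the unpenalised intercept MLE is the prevalence
        # log-odds (saga can terminate before reaching it)
        prevalence = yv.mean()
        intercept = float(np.log(prevalence / (1 - prevalence)))
    else:
        intercept = float(clf.intercept_[0] - (coef_orig * means).sum())
    return ElasticNetModel(
        alpha=alpha,
        lambda_=lambda_,
        coefficients=coef_orig,
        coefficients_std=coef_std.where(usable, 0.0),
        intercept=intercept,
        feature_means=means,
        feature_sds=sds,
    )


def elastic_net_objective(model: ElasticNetModel, X: pd.DataFrame, y) -> float:
    """Mean penalised deviance of a fitted model (standardised scale)."""
    yv = _encode_labels(pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y.loc[X.index])
    Z, _, _ = _standardize(X)
    eta = Z @ model.coefficients_std.to_numpy() + (
        model.intercept + (model.coefficients * model.feature_means).sum()
    )
    nll = np.mean(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - yv * eta)
    c = model.coefficients_std.to_numpy()
    pen = model.lambda_ * (
        model.alpha * np.abs(c).sum() + 0.5 * (1 - model.alpha) * (c**2).sum()
    )
    return float(nll + pen)


def _lambda_path(
    Z: np.ndarray, yv: np.ndarray, alpha: float, n_lambda: int = 15,
    ratio: float = 0.01,
):
    n = len(yv)
    resid = yv - yv.mean()
    lam_max = np.max(np.abs(Z.T @ resid)) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def tune_elastic_net(
    X: pd.DataFrame,
    y,
    alpha_grid=(0.1, 0.4, 0.7, 1.0),
    k_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 15,
) -> tuple[float, float]:
    """Grid/path search for (alpha, lambda) by k-fold CV deviance.

    For each alpha, a geometric lambda path is built from the data-driven
    lambda_max down three decades; folds are stratified by label. The
    solver is warm-started along each fold's descending lambda path, the
    standard trick that keeps cross-validated path fitting fast. The
    (alpha, lambda) pair minimising the mean held-out binomial deviance
    is returned, with ties resolved toward the larger lambda (sparser
    model).
    """
    yv = _encode_labels(pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y.loc[X.index])
    n_min_class = min(np.bincount(yv))
    if k_folds > n_min_class:
        raise ValueError(f"k_folds={k_folds} exceeds smallest class size {n_min_class}")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(yv), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(yv == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k_folds

    Xv = X.to_numpy(float)
    Z_all, _, _ = _standardize(X)
    best = (np.inf, -np.inf, None)  # (deviance, lambda, alpha)
    for alpha in alpha_grid:
        lambdas = _lambda_path(Z_all, yv, alpha, n_lambda)  # descending
        dev = np.zeros((k_folds, len(lambdas)))
        for f in range(k_folds):
            tr, te = folds != f, folds == f
            means = Xv[tr].mean(axis=0)
            sds = Xv[tr].std(axis=0)
            sds[sds == 0] = 1.0
            Ztr = (Xv[tr] - means) / sds
            Zte = (Xv[te] - means) / sds
            n_tr = tr.sum()
            est = LogisticRegression(
                solver="saga", l1_ratio=alpha,
                warm_start=True, max_iter=3000, tol=1e-4,
            )
            for li, lam in enumerate(lambdas):
                est.C = 1.0 / (n_tr * lam)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(Ztr, yv[tr])
                eta = Zte @ est.coef_[0] + est.intercept_[0]
                nll = np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - yv[te] * eta
                dev[f, li] = 2 * nll.mean()
        mean_dev = dev.mean(axis=0)
        for li, lam in enumerate(lambdas):
            key = (round(float(mean_dev[li]), 10), -lam)
            if key < (round(best[0], 10), -best[1]):
                best = (float(mean_dev[li]), lam, alpha)
    return best[2], best[1]


def variable_importance(model: ElasticNetModel) -> pd.Series:
    """Per-feature importance: 100 x |standardised coefficient| scaled to
    the largest; all-zero models give all-zero importances."""
    mags = model.coefficients_std.abs()
    top = mags.max()
    if top == 0:
        return mags * 0.0
    return 100.0 * mags / top


def compute_wmrs(
    beta: pd.DataFrame, weights: pd.Series, train_means: pd.Series, train_sds: pd.Series
) -> pd.Series:
    """Weighted methylation risk score per sample.

    wMRS(s) = sum_i ((beta_i(s) - mean_i) / sd_i) * weight_i over the
    DMPs i, with means/SDs taken from the training samples only. DMPs
    with zero training SD are dropped with a warning.
    """
    dmps = weights.index
    usable = train_sds.loc[dmps] > 0
    if not usable.all():
        warnings.warn(
            f"dropping {(~usable).sum()} DMPs with zero training SD", stacklevel=2
        )
        dmps = dmps[usable]
    z = beta.loc[dmps].sub(train_means.loc[dmps], axis=0).div(train_sds.loc[dmps], axis=0)
    return (z.mul(weights.loc[dmps], axis=0)).sum(axis=0)


def wmrs_model(scores_train: pd.Series, labels_train) -> WmrsModel:
    """Univariate logistic fit of severity on the training wMRS.

    Also runs a two-group rank-sum comparison of the scores. Separation
    falls back to a ridge-penalised fit, flagged.
    """
    yv = _encode_labels(pd.Series(labels_train, index=scores_train.index)
                        if not isinstance(labels_train, pd.Series)
                        else labels_train.loc[scores_train.index])
    if np.ptp(scores_train.to_numpy()) < 1e-15:
        raise ValueError("wMRS scores are degenerate (constant)")
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(yv)), scores_train.to_numpy(float)])
    flag = ""
    try:
        fit = sm.Logit(yv, X).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True) or np.any(np.isnan(fit.bse)):
            raise np.linalg.LinAlgError
        coefs, pvals = fit.params, fit.pvalues
    except Exception:
        coefs, pvals = _ridge_logit(yv.astype(float), X)
        flag = "separation"
    model = WmrsModel(
        weights=pd.Series(dtype=float),
        train_means=pd.Series(dtype=float),
        train_sds=pd.Series(dtype=float),
        coefficient=float(coefs[1]),
        intercept=float(coefs[0]),
        p_value=float(pvals[1]),
        flag=flag,
    )
    return model


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC from continuous scores.

    AUC equals the normalised Mann-Whitney statistic:
    (concordant + 0.5 x tied pairs) / (n_pos x n_neg). The curve sweeps
    the sorted unique scores as thresholds (predict positive when
    score >= threshold).
    """
    s = np.asarray(pd.Series(scores), dtype=float)
    yv = _encode_labels(pd.Series(labels))
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    pos, neg = s[yv == 1], s[yv == 0]
    ranks = stats.rankdata(s)
    auc = (ranks[yv == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocResult(thresholds=thresholds, sensitivities=sens,
                     specificities=spec, auc=float(auc))


def compare_models(
    clinical_X: pd.DataFrame,
    methylation_X: pd.DataFrame,
    dmp_weights: pd.Series,
    labels: pd.Series,
    split: tuple[list, list],
    alpha_grid=(0.1, 0.4, 0.7, 1.0),
    k_folds: int = 5,
    seed: int = 0,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Train and evaluate the three severity classifiers on one split.

    Models 1 and 2 are CV-tuned elastic nets on the clinical and
    methylation feature tables; model 3 standardises the DMP beta values
    with training-set statistics and scores the wMRS. All training
    statistics are computed on the training ids only; any overlap
    between train and test ids raises. Returns a dict with the fitted
    models, per-model test AUC, variable importances, and the overlap of
    model-2 selected CpGs with the discovery DMPs (gene-level too when
    an annotation is supplied).
    """
    train_ids, test_ids = split
    if set(train_ids) & set(test_ids):
        raise ValueError("leakage: train and test ids overlap")
    lab = pd.Series(labels)
    y_train, y_test = lab.loc[train_ids], lab.loc[test_ids]

    results: dict = {"auc": {}}

    # model 1: clinical elastic net
    a1, l1 = tune_elastic_net(clinical_X.loc[train_ids], y_train,
                              alpha_grid=alpha_grid, k_folds=k_folds, seed=seed)
    m1 = fit_elastic_net(clinical_X.loc[train_ids], y_train, a1, l1)
    roc1 = roc_auc(m1.decision_function(clinical_X.loc[test_ids]), y_test)
    results["model1"] = m1
    results["roc1"] = roc1
    results["auc"]["clinical"] = roc1.auc

    # model 2: methylation elastic net
    a2, l2 = tune_elastic_net(methylation_X.loc[train_ids], y_train,
                              alpha_grid=alpha_grid, k_folds=k_folds, seed=seed)
    m2 = fit_elastic_net(methylation_X.loc[train_ids], y_train, a2, l2)
    roc2 = roc_auc(m2.decision_function(methylation_X.loc[test_ids]), y_test)
    results["model2"] = m2
    results["roc2"] = roc2
    results["auc"]["methylation"] = roc2.auc
    selected = set(m2.selected_features)
    overlap_cpg = sorted(selected & set(dmp_weights.index))
    results["model2_dmp_overlap_cpg"] = overlap_cpg
    if annotation is not None:
        ann = annotation.set_index("probe_id") if "probe_id" in annotation else annotation
        genes_sel = {
            g for g in ann.reindex(sorted(selected & set(ann.index)))["gene"] if g
        }
        genes_dmp = {
            g
            for g in ann.reindex(sorted(set(dmp_weights.index) & set(ann.index)))["gene"]
            if g
        }
        results["model2_dmp_overlap_gene"] = sorted(genes_sel & genes_dmp)

    # model 3: wMRS
    beta_all = methylation_X.T  # features x samples view for scoring
    dmps = dmp_weights.index.intersection(beta_all.index)
    train_beta = beta_all.loc[dmps, train_ids]
    means, sds = train_beta.mean(axis=1), train_beta.std(axis=1, ddof=0)
    scores_train = compute_wmrs(beta_all[train_ids], dmp_weights.loc[dmps], means, sds)
    scores_test = compute_wmrs(beta_all[test_ids], dmp_weights.loc[dmps], means, sds)
    m3 = wmrs_model(scores_train, y_train)
    m3.weights = dmp_weights.loc[dmps]
    m3.train_means, m3.train_sds = means, sds
    roc3 = roc_auc(scores_test, y_test)
    results["model3"] = m3
    results["roc3"] = roc3
    results["auc"]["wmrs"] = roc3.auc
    results["wmrs_scores_train"] = scores_train
    results["wmrs_scores_test"] = scores_test
    return results
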