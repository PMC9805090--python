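"""Per-CpG differential methylation between severity groups.

The primary test regresses severity group (mild = 0, severe = 1) on the
beta value at each probe plus adjustment covariates (by default the NK
cell proportion) in a logistic model, and reports the Wald p-value of
the methylation coefficient. A linear alternative (M-value as outcome,
group as predictor) is available through ``mode="linear"``. Differences
are reported as delta_meth = mean beta(severe) - mean beta(mild), so a
positive value means hypermethylated in the severe group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from ._utils import beta_to_m, m_to_beta  # noqa: F401  (shared utilities)
from .containers import validate_annotation

DMP_FDR_MAX = 0.05
DMP_MIN_DELTA = 0.01
MAJOR_DELTA = 0.05


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorts p ascending, takes p(i) * m / i, enforces monotonicity from the
    largest rank down, caps at 1 and restores the input order. Empty
    input returns an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def _ridge_logit(y: np.ndarray, X: np.ndarray, lam: float = 1e-3):
    """Ridge-penalised logistic fit by IRLS; returns (coef, wald_p per coef).

    Used as the fallback when the unpenalised fit separates. The Wald
    covariance is the inverse penalised information matrix; the intercept
    (column 0) is not penalised.
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = lam * np.eye(k)
    pen[0, 0] = 0.0
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        info = X.T @ (X * w[:, None]) + 2 * pen
        grad = X.T @ (y - mu) - 2 * pen @ beta
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return beta, p


def test_dmps(
    beta: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    mode: str = "logistic",
) -> pd.DataFrame:
    """Per-probe differential methylation test with BH-FDR adjustment.

    Parameters
    ----------
    beta : probes x samples beta values.
    labels : per-sample "mild"/"severe" (or 0/1) labels.
    covariates : per-sample adjustment columns (e.g. NK proportion).
    mode : "logistic" regresses group on beta + covariates (default);
        "linear" regresses the probe M-value on group + covariates.

    Returns a DataFrame indexed by probe with columns delta_meth,
    p_value, fdr, direction (hyper/hypo in severe), is_major and flag
    ("separation" where the penalised fallback was used, "constant" for
    invariant probes with p = 1).
    """
    labels = pd.Series(labels).loc[beta.columns]
    y = _encode_labels(labels)
    severe = beta.columns[y == 1]
    mild = beta.columns[y == 0]
    if len(severe) == 0 or len(mild) == 0:
        raise ValueError("both severity groups must be present")

    cov = None
    if covariates is not None and len(covariates.columns):
        cov = covariates.loc[beta.columns].to_numpy(float)

    delta = beta[severe].mean(axis=1) - beta[mild].mean(axis=1)
    mvals = beta_to_m(beta) if mode == "linear" else None

    pvals = np.ones(len(beta.index))
    flags = np.array([""] * len(beta.index), dtype=object)
    for i, probe in enumerate(beta.index):
        x = beta.loc[probe].to_numpy(float)
        if np.ptp(x) < 1e-12:
            flags[i] = "constant"
            continue
        if mode == "logistic":
            cols = [np.ones_like(x), x]
            if cov is not None:
                cols.extend(cov.T)
            X = np.column_stack(cols)
            try:
                with warnings.catch_warnings():
                    # separation inflates Wald SEs (Hauck-Donner); escalate
                    # the statsmodels warning so the ridge fallback kicks in
                    warnings.simplefilter("error", PerfectSeparationWarning)
                    warnings.simplefilter("ignore", category=UserWarning)
                    warnings.simplefilter("ignore", category=RuntimeWarning)
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                if not fit.mle_retvals.get("converged", True):
                    raise np.linalg.LinAlgError
                pvals[i] = fit.pvalues[1]
                if np.isnan(pvals[i]) or np.abs(fit.params).max() > 1e3:
                    raise np.linalg.LinAlgError
            except Exception:
                _, p = _ridge_logit(y.astype(float), X)
                pvals[i] = p[1]
                flags[i] = "separation"
        elif mode == "linear":
            cols = [np.ones_like(x), y.astype(float)]
            if cov is not None:
                cols.extend(cov.T)
            X = np.column_stack(cols)
            fit = sm.OLS(mvals.loc[probe].to_numpy(float), X).fit()
            pvals[i] = fit.pvalues[1]
        else:
            raise ValueError(f"unknown mode {mode!r}")

    fdr = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "delta_meth": delta.to_numpy(),
            "p_value": pvals,
            "fdr": fdr,
            "direction": np.where(delta.to_numpy() >= 0, "hyper", "hypo"),
            "is_major": _is_major(delta.to_numpy()),
            "flag": flags,
        },
        index=beta.index.rename("probe_id"),
    )


def _encode_labels(labels: pd.Series) -> np.ndarray:
    vals = labels.astype(str).str.lower()
    if set(vals.unique()) <= {"mild", "severe"}:
        return (vals == "severe").to_numpy(int)
    numeric = pd.to_numeric(labels)
    uniq = set(numeric.unique())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be mild/severe or 0/1, got {sorted(uniq)}")
    return numeric.to_numpy(int)


def _is_major(delta: np.ndarray, major_delta: float = MAJOR_DELTA) -> np.ndarray:
    # |delta| rounded to 3 dp at or above the 5% bound counts as major,
    # so a printed 0.050 qualifies
    return np.round(np.abs(delta), 3) >= major_delta


def filter_dmps(
    results: pd.DataFrame,
    fdr_max: float = DMP_FDR_MAX,
    min_delta: float = DMP_MIN_DELTA,
    major_delta: float = MAJOR_DELTA,
) -> pd.DataFrame:
    """Keep probes with FDR strictly below ``fdr_max`` and |delta_meth|
    strictly above ``min_delta``; re-mark is_major at ``major_delta``."""
    keep = (results["fdr"] < fdr_max) & (results["delta_meth"].abs() > min_delta)
    out = results.loc[keep].copy()
    out["is_major"] = _is_major(out["delta_meth"].to_numpy(), major_delta)
    return out


def annotate_context(dmps: pd.DataFrame, annotation: pd.DataFrame) -> dict:
    """CGI-context and direction tallies for a DMP list.

    Returns a dict with per-context counts and percentages (1 dp) and
    the hyper/hypo split (percentages rounded to whole numbers as in the
    conventional reporting of direction splits).
    """
    ann = validate_annotation(annotation)
    missing = dmps.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing for DMPs: {sorted(missing)[:10]}")
    n = len(dmps)
    contexts = ("opensea", "shore", "shelf", "island")
    counts = {c: 0 for c in contexts}
    if n:
        vc = ann.loc[dmps.index, "cgi_context"].value_counts()
        counts.update({c: int(vc.get(c, 0)) for c in contexts})
    n_hyper = int((dmps["delta_meth"] > 0).sum()) if n else 0
    n_hypo = int((dmps["delta_meth"] < 0).sum()) if n else 0

    def pct(x, digits=1):
        return round(100.0 * x / n, digits) if n else 0.0

    return {
        "n_dmps": n,
        "context_counts": counts,
        "context_pct": {c: pct(counts[c]) for c in contexts},
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": pct(n_hyper, 0),
        "pct_hypo": pct(n_hypo, 0),
    }


def exclude_smoking_cpgs(
    dmps: pd.DataFrame, smoking_list
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop DMPs that appear in a user-supplied smoking-associated CpG list.

    Returns (retained, removed); removed is the intersection with the
    list, reported so the exclusion is auditable.
    """
    smoking = set(smoking_list)
    removed_idx = dmps.index[dmps.index.isin(smoking)]
    return dmps.drop(removed_idx), dmps.loc[removed_idx]


def match_pairs_by_age(
    ages: pd.Series, labels: pd.Series, max_age_gap: float = 2.0
) -> list[tuple[str, str]]:
    """Greedy nearest-age 1:1 matching of mild to severe samples.

    Mild samples are visited in age order; each takes the nearest unused
    severe sample within ``max_age_gap`` years. Each sample is used at
    most once; unmatched samples are dropped.
    """
    lab = labels.astype(str).str.lower()
    mild = ages[lab == "mild"].sort_values()
    severe = ages[lab == "severe"].sort_values()
    used: set = set()
    pairs = []
    for mid, mage in mild.items():
        best, best_gap = None, np.inf
        for sid, sage in severe.items():
            if sid in used:
                continue
            gap = abs(sage - mage)
            if gap < best_gap:
                best, best_gap = sid, gap
        if best is not None and best_gap <= max_age_gap:
            used.add(best)
            pairs.append((mid, best))
    return pairs


def matched_pair_sensitivity(
    beta: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    max_age_gap: float = 2.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Covariate sensitivity analysis on age-matched mild-severe pairs.

    Samples are 1:1 matched on age; per pair and probe the methylation
    difference delta = beta(severe) - beta(mild) is computed. For each
    continuous covariate the per-pair covariate difference is tested for
    Pearson correlation with delta at every probe; categorical covariates
    are tested by one-way ANOVA of delta across levels, restricted to
    pairs concordant on that covariate (skipped when no two levels have
    concordant pairs). P-values are BH-adjusted within each covariate.

    ``phenotypes`` needs columns sample_id, label and age; covariates is
    indexed by sample_id. Returns (long association table, pairs used).
    """
    pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes else phenotypes
    pairs = match_pairs_by_age(pheno["age"], pheno["label"], max_age_gap)
    if not pairs:
        raise ValueError("no age-matched pairs could be formed")
    mild_ids = [p[0] for p in pairs]
    severe_ids = [p[1] for p in pairs]
    delta = beta[severe_ids].to_numpy() - beta[mild_ids].to_numpy()  # probes x pairs

    rows = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cov_diff = col.loc[severe_ids].to_numpy(float) - col.loc[mild_ids].to_numpy(float)
            if np.ptp(cov_diff) < 1e-12:
                continue  # matched exactly; nothing to correlate
            stats_p = [stats.pearsonr(delta[i], cov_diff) for i in range(delta.shape[0])]
            pvals = np.array([sp[1] for sp in stats_p])
            estimates = np.array([sp[0] for sp in stats_p])
            kind = "pearson"
        else:
            concordant = [
                k
                for k in range(len(pairs))
                if col.loc[mild_ids[k]] == col.loc[severe_ids[k]]
            ]
            if not concordant:
                continue
            values = col.loc[[mild_ids[k] for k in concordant]].to_numpy()
            levels = pd.unique(values)
            if len(levels) < 2 or min((values == lv).sum() for lv in levels) < 2:
                continue
            sub = delta[:, concordant]
            pvals = np.empty(sub.shape[0])
            estimates = np.full(sub.shape[0], np.nan)
            for i in range(sub.shape[0]):
                groups = [sub[i][values == lv] for lv in levels]
                _, pvals[i] = stats.f_oneway(*groups)
            kind = "anova"
        fdr = bh_fdr(pvals)
        for i, probe in enumerate(beta.index):
            rows.append(
                {
                    "covariate": name,
                    "probe_id": probe,
                    "test": kind,
                    "estimate": estimates[i],
                    "p_value": pvals[i],
                    "fdr": fdr[i],
                }
            )
    return pd.DataFrame(rows), pairs
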