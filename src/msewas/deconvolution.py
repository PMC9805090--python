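"""Reference-based leukocyte deconvolution and cell-type-specific DMPs.

Whole-blood methylation is a mixture of cell-type-specific profiles.
Given reference beta profiles for the six major leukocyte types (CD4 T,
CD8 T, B, NK, monocyte, granulocyte), per-sample proportions are
estimated by non-negative constrained least squares on marker probes and
renormalised to sum to one. A proportion x phenotype interaction model
then asks, per probe and per cell type, whether the severity effect is
carried by that cell type (csDMPs) at the genome-wide threshold
p <= 9e-8.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

CELL_TYPES = ("CD4T", "CD8T", "B", "NK", "monocyte", "granulocyte")
CSDMP_ALPHA = 9e-8


def select_marker_probes(reference: pd.DataFrame, per_type: int = 100) -> pd.Index:
    """Pick discriminating probes: for each cell type, the probes where it
    deviates most from the mean of the other types (top ``per_type`` by
    absolute deviation), unioned across types."""
    markers: pd.Index = pd.Index([])
    for ct in reference.columns:
        others = reference.drop(columns=ct).mean(axis=1)
        dev = (reference[ct] - others).abs().sort_values(ascending=False)
        markers = markers.union(dev.index[:per_type])
    return markers


def estimate_proportions(beta: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Constrained least-squares mixture estimation per sample.

    Fits each sample's beta vector (restricted to the reference's marker
    probes) as a non-negative combination of the reference columns and
    renormalises the weights to sum to one. Requires at least as many
    shared probes as cell types and a full-rank reference.
    """
    shared = reference.index.intersection(beta.index)
    if len(shared) < reference.shape[1]:
        raise ValueError("fewer shared marker probes than cell types")
    R = reference.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        corr = np.corrcoef(R.T)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "reference profiles are rank-deficient; most collinear columns: "
            f"{reference.columns[i]} and {reference.columns[j]}"
        )
    out = np.empty((beta.shape[1], R.shape[1]))
    B = beta.loc[shared].to_numpy(float)
    for s in range(B.shape[1]):
        w, _ = nnls(R, B[:, s])
        total = w.sum()
        out[s] = w / total if total > 0 else np.full(R.shape[1], 1.0 / R.shape[1])
    return pd.DataFrame(out, index=beta.columns, columns=reference.columns)


def compare_proportions(proportions: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-group comparison of each cell type's proportions.

    Uses a t-test when Shapiro-Wilk keeps normality in both groups
    (p > 0.05), a Wilcoxon rank-sum test otherwise; BH adjustment across
    cell types.
    """
    lab = pd.Series(labels).loc[proportions.index].astype(str).str.lower()
    groups = lab.unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1 = proportions[lab == groups[0]]
    g2 = proportions[lab == groups[1]]
    rows = []
    for ct in proportions.columns:
        x, y = g1[ct].to_numpy(), g2[ct].to_numpy()
        normal = (
            min(len(x), len(y)) >= 3
            and np.ptp(x) > 0
            and np.ptp(y) > 0
            and stats.shapiro(x).pvalue > 0.05
            and stats.shapiro(y).pvalue > 0.05
        )
        if np.ptp(np.concatenate([x, y])) < 1e-15:
            test, stat, p = "none", 0.0, 1.0
        elif normal:
            res = stats.ttest_ind(x, y)
            test, stat, p = "t", float(res.statistic), float(res.pvalue)
        else:
            res = stats.ranksums(x, y)
            test, stat, p = "ranksum", float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "cell_type": ct,
                "test": test,
                "statistic": stat,
                "mean_diff": float(x.mean() - y.mean()),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("cell_type")
    from .dmp import bh_fdr

    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    return table


def cell_specific_dmps(
    m_values: pd.DataFrame,
    proportions: pd.DataFrame,
    labels: pd.Series,
    alpha: float = CSDMP_ALPHA,
) -> pd.DataFrame:
    """Interaction-model scan for cell-type-specific severity effects.

    Per probe, fits the no-intercept linear model

        M ~ sum_k w_k + sum_k (w_k x severity)

    where w_k is the estimated proportion of cell type k and severity is
    0/1. Because the w_k sum to one per sample, the full set of
    proportion columns replaces the intercept and the design stays
    full-rank without dropping a type; each type keeps its own
    interaction test. Returns a long table (probe_id, cell_type,
    coefficient, p_value, significant) with significance at p <= alpha
    (genome-wide 9e-8 by default). Collinear designs mark the probe's
    rows with flag="collinear" and NaN statistics.
    """
    from .dmp import _encode_labels

    lab = _encode_labels(pd.Series(labels).loc[m_values.columns])
    W = proportions.loc[m_values.columns].to_numpy(float)  # samples x K
    K = W.shape[1]
    X = np.concatenate([W, W * lab[:, None]], axis=1)  # samples x 2K
    names = list(proportions.columns)

    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    rows = []
    if rank < 2 * K:
        for probe in m_values.index:
            for k, ct in enumerate(names):
                rows.append(
                    {"probe_id": probe, "cell_type": ct, "coefficient": np.nan,
                     "p_value": np.nan, "significant": False, "flag": "collinear"}
                )
        return pd.DataFrame(rows)

    xtx_inv = np.linalg.inv(xtx)
    H = xtx_inv @ X.T
    n = X.shape[0]
    dof = n - 2 * K
    Y = m_values.to_numpy(float)  # probes x samples
    coefs = Y @ H.T  # probes x 2K
    resid = Y - coefs @ X.T
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coefs / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)

    for i, probe in enumerate(m_values.index):
        for k, ct in enumerate(names):
            j = K + k  # interaction column for type k
            rows.append(
                {
                    "probe_id": probe,
                    "cell_type": ct,
                    "coefficient": float(coefs[i, j]),
                    "p_value": float(pvals[i, j]),
                    "significant": bool(pvals[i, j] <= alpha),
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)
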