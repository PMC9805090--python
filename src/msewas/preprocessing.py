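"""Methylation array preprocessing: QC filters, BMIQ-style type-II
normalisation, SVD batch-effect detection and empirical-Bayes (ComBat)
batch correction.

All filters operate on a MethylationMatrix and a probe annotation table;
normalisation and correction work on beta values and M-values
respectively, always returning matrices of the same shape and ids
(filters excepted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc

from ._utils import beta_to_m, clip_beta, m_to_beta
from .containers import MethylationMatrix, validate_annotation

logger = logging.getLogger(__name__)

DETECTION_P_MAX = 0.01
MIN_BEAD_COUNT = 3
PROBE_FAIL_FRACTION = 0.05
SAMPLE_FAIL_RATIO = 0.1


@dataclass
class ProbeFilterReport:
    """Per-rule removal counts from filter_probes; rules are applied as a
    union, each probe attributed to every rule it violates."""

    detection_p: int = 0
    bead_count: int = 0
    non_cpg: int = 0
    snp_related: int = 0
    multi_hit: int = 0
    non_autosomal: int = 0
    total_removed: int = 0
    removed_ids: dict = field(default_factory=dict)


def filter_probes(
    m: MethylationMatrix, annotation: pd.DataFrame
) -> tuple[MethylationMatrix, ProbeFilterReport]:
    """Remove low-quality and problematic probes.

    A probe is removed when any of the following holds:

    * detection p-value > 0.01 in >= 5% of samples,
    * bead count < 3 in >= 5% of samples,
    * it is flagged non-CpG, SNP-related or multi-hit in the annotation,
    * it is not autosomal.

    Returns the filtered matrix and a report with removal counts per rule
    (a probe failing several rules is counted under each; total_removed
    counts unique probes).
    """
    ann = validate_annotation(annotation)
    missing = m.probes.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing for probes: {sorted(missing)[:10]}")
    ann = ann.loc[m.probes]
    n = m.n_samples

    removed: dict[str, pd.Index] = {}
    if m.detection_p is not None:
        fail_frac = (m.detection_p > DETECTION_P_MAX).sum(axis=1) / n
        removed["detection_p"] = m.probes[fail_frac >= PROBE_FAIL_FRACTION]
    if m.bead_count is not None:
        low_frac = (m.bead_count < MIN_BEAD_COUNT).sum(axis=1) / n
        removed["bead_count"] = m.probes[low_frac >= PROBE_FAIL_FRACTION]
    removed["non_cpg"] = m.probes[ann["non_cpg"].astype(bool)]
    removed["snp_related"] = m.probes[ann["snp_related"].astype(bool)]
    removed["multi_hit"] = m.probes[ann["multi_hit"].astype(bool)]
    removed["non_autosomal"] = m.probes[~ann["autosomal"].astype(bool)]

    all_removed = pd.Index([])
    for ids in removed.values():
        all_removed = all_removed.union(ids)
    keep = m.probes.difference(all_removed)
    report = ProbeFilterReport(
        detection_p=len(removed.get("detection_p", [])),
        bead_count=len(removed.get("bead_count", [])),
        non_cpg=len(removed["non_cpg"]),
        snp_related=len(removed["snp_related"]),
        multi_hit=len(removed["multi_hit"]),
        non_autosomal=len(removed["non_autosomal"]),
        total_removed=len(all_removed),
        removed_ids={k: list(v) for k, v in removed.items()},
    )
    return m.subset_probes(keep), report


def filter_samples(m: MethylationMatrix) -> tuple[MethylationMatrix, list[str]]:
    """Remove samples with a failed-to-successful probe ratio above 0.1.

    A probe "fails" in a sample when its detection p-value exceeds 0.01;
    the ratio is (#failed)/(#passing) within that sample.
    """
    if m.detection_p is None:
        raise ValueError("detection_p channel required for sample filtering")
    failed = (m.detection_p > DETECTION_P_MAX).sum(axis=0)
    passing = m.n_probes - failed
    ratio = failed / passing.replace(0, np.nan)
    bad = m.samples[(ratio > SAMPLE_FAIL_RATIO) | passing.eq(0)]
    if len(bad) == m.n_samples:
        raise RuntimeError("all samples failed the detection-ratio filter")
    return m.subset_samples(m.samples.difference(bad)), list(bad)


# ---------------------------------------------------------------------------
# BMIQ-style normalisation
# ---------------------------------------------------------------------------


def _fit_beta_mixture(x, n_states=3, max_iter=100, tol=1e-4, seed=0):
    """EM fit of an n-state beta mixture; returns (weights, a, b, converged).

    States are initialised by k-means-style quantile seeding with a fixed
    seed and kept ordered by mean so state 0 is the unmethylated mode and
    state n-1 the methylated mode. The M-step uses method-of-moments
    updates of the beta shape parameters from the posterior-weighted
    means/variances (EM on the responsibilities; tolerance on mean
    log-likelihood change).
    """
    x = np.clip(np.asarray(x, float), 1e-4, 1 - 1e-4)
    rng = np.random.default_rng(seed)
    # quantile-based initial partition, jittered assignments like k-means init
    qs = np.quantile(x, np.linspace(0, 1, n_states + 1))
    assign = np.clip(np.searchsorted(qs[1:-1], x), 0, n_states - 1)
    assign = np.where(rng.random(x.size) < 0.02, rng.integers(0, n_states, x.size), assign)

    w = np.full(n_states, 1.0 / n_states)
    a = np.empty(n_states)
    b = np.empty(n_states)
    for k in range(n_states):
        xk = x[assign == k]
        mu = xk.mean() if xk.size else (k + 0.5) / n_states
        var = xk.var() if xk.size > 1 else 0.01
        var = min(max(var, 1e-5), mu * (1 - mu) * 0.95)
        nu = mu * (1 - mu) / var - 1
        a[k], b[k] = max(mu * nu, 0.05), max((1 - mu) * nu, 0.05)

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        logpdf = np.stack(
            [stats.beta.logpdf(x, a[k], b[k]) + np.log(w[k]) for k in range(n_states)]
        )
        norm = np.logaddexp.reduce(logpdf, axis=0)
        resp = np.exp(logpdf - norm)
        ll = norm.mean()
        nk = resp.sum(axis=1) + 1e-12
        w = nk / nk.sum()
        mu = resp @ x / nk
        var = resp @ (x**2) / nk - mu**2
        var = np.clip(var, 1e-5, mu * (1 - mu) * 0.95)
        nu = mu * (1 - mu) / var - 1
        a = np.maximum(mu * nu, 0.05)
        b = np.maximum((1 - mu) * nu, 0.05)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    order = np.argsort(a / (a + b))
    return w[order], a[order], b[order], converged


def bmiq_normalize(
    m: MethylationMatrix, max_iter: int = 100, tol: float = 1e-4
) -> MethylationMatrix:
    """Beta-mixture quantile normalisation of type-II probes onto type-I.

    For each sample, three-state beta mixtures (unmethylated / hemi /
    methylated) are fitted by EM to the type-I and type-II beta
    distributions separately. Each type-II value is assigned to its
    maximum-posterior state and mapped through the state-wise quantile
    transform x' = F_I^{-1}(F_II(x)) between the fitted beta components,
    which is monotone within each state. Type-I probes pass through
    unchanged. If either EM fails to converge the sample is left
    untouched with a logged warning.
    """
    if m.design_type is None:
        raise ValueError("design_type required for BMIQ normalisation")
    type1 = m.probes[m.design_type.loc[m.probes] == "I"]
    type2 = m.probes[m.design_type.loc[m.probes] == "II"]
    if len(type1) < 100 or len(type2) < 100:
        raise ValueError("need >= 100 probes of each design type")

    beta = m.beta.copy()
    for j, sample in enumerate(m.samples):
        x1 = beta.loc[type1, sample].to_numpy()
        x2 = beta.loc[type2, sample].to_numpy()
        w1, a1, b1, ok1 = _fit_beta_mixture(x1, max_iter=max_iter, tol=tol, seed=j)
        w2, a2, b2, ok2 = _fit_beta_mixture(x2, max_iter=max_iter, tol=tol, seed=j)
        if not (ok1 and ok2):
            logger.warning("BMIQ EM did not converge for sample %s; left unchanged", sample)
            continue
        x2c = np.clip(x2, 1e-4, 1 - 1e-4)
        logpost = np.stack(
            [stats.beta.logpdf(x2c, a2[k], b2[k]) + np.log(w2[k]) for k in range(3)]
        )
        state = np.argmax(logpost, axis=0)
        out = x2c.copy()
        for k in range(3):
            sel = state == k
            if not sel.any():
                continue
            u = betainc(a2[k], b2[k], x2c[sel])
            out[sel] = stats.beta.ppf(np.clip(u, 1e-12, 1 - 1e-12), a1[k], b1[k])
        beta.loc[type2, sample] = np.clip(out, 1e-6, 1 - 1e-6)
    return MethylationMatrix(
        beta=beta,
        design_type=m.design_type,
        detection_p=m.detection_p,
        bead_count=m.bead_count,
    )


# ---------------------------------------------------------------------------
# batch effects
# ---------------------------------------------------------------------------


def svd_batch_detect(
    m: MethylationMatrix, technical_factors: pd.DataFrame, n_components: int = 10
) -> pd.DataFrame:
    """Associate top singular components of the M matrix with technical factors.

    The probe-centred M matrix is decomposed by SVD; for each of the top
    ``n_components`` right singular vectors, each categorical factor is
    tested by one-way ANOVA across its levels and each continuous factor
    by a Pearson correlation test. Returns a long table (component,
    factor, p_value, significant) where significant means p < 0.01.
    Constant factors are skipped with a note row (p = NaN).
    """
    mat = m.m.to_numpy()
    centred = mat - mat.mean(axis=1, keepdims=True)
    k = min(n_components, min(centred.shape) - 1)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    components = vt[:k]

    rows = []
    for name in technical_factors.columns:
        col = technical_factors.loc[m.samples, name]
        categorical = not pd.api.types.is_numeric_dtype(col)
        if col.nunique() < 2:
            rows.append({"component": None, "factor": name, "p_value": np.nan,
                         "significant": False, "note": "constant factor skipped"})
            continue
        if categorical:
            levels = [g.to_numpy() for _, g in pd.Series(range(len(col))).groupby(col.to_numpy())]
            if min(len(g) for g in levels) < 2:
                rows.append({"component": None, "factor": name, "p_value": np.nan,
                             "significant": False, "note": "level with < 2 samples skipped"})
                continue
        for i in range(k):
            comp = components[i]
            if categorical:
                groups = [comp[idx] for idx in levels]
                _, p = stats.f_oneway(*groups)
            else:
                _, p = stats.pearsonr(comp, col.to_numpy(float))
            rows.append({"component": i + 1, "factor": name, "p_value": float(p),
                         "significant": bool(p < 0.01), "note": ""})
    return pd.DataFrame(rows)


def _combat_it_sol(z, g_hat, d_hat, g_bar, t2, a_prior, b_prior, tol=1e-4):
    """Iterative solution of the parametric empirical-Bayes batch estimates."""
    n = (~np.isnan(z)).sum(axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > tol:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((z - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-12)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_correct(m: MethylationMatrix, batch: pd.Series) -> MethylationMatrix:
    """Parametric empirical-Bayes (ComBat) batch correction on M-values.

    Probe-wise, M-values are standardised against the grand (batch-size
    weighted) mean and pooled variance; per-batch location (gamma) and
    scale (delta^2) effects are estimated and shrunk toward normal /
    inverse-gamma priors fitted across probes by the method of moments;
    standardised data are adjusted and the grand scale restored. Beta
    values are recovered through the inverse logit.
    """
    batch = pd.Series(batch).loc[m.samples]
    levels = batch.unique()
    if len(levels) < 2:
        raise ValueError("combat_correct needs >= 2 batches")
    counts = batch.value_counts()
    if (counts < 2).any():
        ones = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with a single sample: {ones}")

    x = m.m.to_numpy()
    n_probes, n_samples = x.shape
    design = pd.get_dummies(batch).loc[m.samples, levels].to_numpy(float)  # samples x batches
    n_per = design.sum(axis=0)

    # probe-wise batch means and grand (weighted) mean
    batch_means = (x @ design) / n_per  # probes x batches
    grand_mean = batch_means @ (n_per / n_samples)
    resid = x - batch_means @ design.T
    pooled_var = (resid**2).sum(axis=1) / n_samples
    pooled_var = np.maximum(pooled_var, 1e-12)
    z = (x - grand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

    adjusted = np.empty_like(z)
    for j, level in enumerate(levels):
        idx = design[:, j] == 1
        zb = z[:, idx]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        d_bar, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2 * s2 + d_bar**2) / s2
        b_prior = (d_bar * s2 + d_bar**3) / s2
        g_star, d_star = _combat_it_sol(zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        adjusted[:, idx] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    corrected = adjusted * np.sqrt(pooled_var)[:, None] + grand_mean[:, None]
    beta = m_to_beta(pd.DataFrame(corrected, index=m.probes, columns=m.samples))
    return MethylationMatrix(
        beta=clip_beta(beta),
        design_type=m.design_type,
        detection_p=m.detection_p,
        bead_count=m.bead_count,
    )
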