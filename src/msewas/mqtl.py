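"""Genotype QC and targeted methylation-QTL analysis.

SNVs are stored as allele counts {0, 1, 2} (missing = NaN) in a
samples x SNV table plus a metadata table (chromosome, 1-based position,
alleles). QC applies the standard call-rate / MAF / Hardy-Weinberg /
monomorphism / autosome rules; the mQTL scan tests methylation beta
values against genotype classes with Kruskal-Wallis (methylation betas
are not normal), and genotype-adjusted logistic models ask whether the
methylation-severity association survives adjustment for local genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

CALL_RATE_MIN = 0.95
MAF_MIN = 0.05
HWE_P_MIN = 1e-5
CIS_WINDOW = 5000


@dataclass
class GenotypeQCReport:
    call_rate: int = 0
    maf: int = 0
    hwe: int = 0
    monomorphic: int = 0
    non_autosomal: int = 0
    samples_removed: list = field(default_factory=list)
    total_snvs_removed: int = 0


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, exact_threshold: float = 5.0) -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    Uses the 1-df chi-square test against expected counts from the
    observed allele frequencies; switches to the exact conditional test
    (summing heterozygote-count probabilities no more likely than the
    observed one) when any expected count falls below
    ``exact_threshold``.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    expected = n * np.array([p**2, 2 * p * q, q**2])
    if np.any(expected < exact_threshold):
        return _hwe_exact(int(n_AA), int(n_Aa), int(n_aa))
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE test: conditional distribution of the heterozygote count
    given allele counts, summing probabilities <= that of the observed."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (orientation irrelevant)
    n_a = min(n_a, 2 * n - n_a)
    het_values = [h for h in range(n_a % 2, n_a + 1, 2)]
    from math import lgamma

    def log_prob(h):
        hom_rare = (n_a - h) // 2
        hom_common = n - h - hom_rare
        return (
            lgamma(n + 1)
            - lgamma(hom_rare + 1)
            - lgamma(hom_common + 1)
            - lgamma(h + 1)
            + h * np.log(2)
            + lgamma(n_a + 1)
            + lgamma(2 * n - n_a + 1)
            - lgamma(2 * n + 1)
        )

    logs = np.array([log_prob(h) for h in het_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    if n_Aa not in het_values:
        return 0.0
    obs_idx = het_values.index(n_Aa)
    return float(min(1.0, probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum()))


def _maf(col: pd.Series) -> float:
    vals = col.dropna().to_numpy(float)
    if vals.size == 0:
        return 0.0
    freq = vals.sum() / (2 * vals.size)
    return min(freq, 1 - freq)


def genotype_qc(
    genotypes: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeQCReport]:
    """Apply SNV- and sample-level QC.

    SNVs are dropped, in order, by: call rate < 95%, MAF < 5% (strict),
    Hardy-Weinberg p < 1e-5, monomorphism, and non-autosomal location;
    each SNV is counted under the first rule that removes it. Samples
    with call rate < 95% (over the retained SNVs) are then dropped.
    Returns (genotypes, metadata, report).
    """
    report = GenotypeQCReport()
    g = genotypes.copy()
    meta = metadata.copy()
    if "snv_id" in meta.columns:
        meta = meta.set_index("snv_id")
    meta = meta.loc[g.columns]

    keep = []
    autosomes = {str(c) for c in range(1, 23)}
    for snv in g.columns:
        col = g[snv]
        call_rate = col.notna().mean()
        if call_rate < CALL_RATE_MIN:
            report.call_rate += 1
            continue
        if _maf(col) < MAF_MIN:
            report.maf += 1
            continue
        vals = col.dropna()
        n_AA, n_Aa, n_aa = (vals == 0).sum(), (vals == 1).sum(), (vals == 2).sum()
        if hwe_test(n_AA, n_Aa, n_aa) < HWE_P_MIN:
            report.hwe += 1
            continue
        if vals.nunique() < 2:
            report.monomorphic += 1
            continue
        if str(meta.loc[snv, "chromosome"]) not in autosomes:
            report.non_autosomal += 1
            continue
        keep.append(snv)
    g = g[keep]
    meta = meta.loc[keep]
    report.total_snvs_removed = len(genotypes.columns) - len(keep)

    if len(keep):
        sample_call = g.notna().mean(axis=1)
        bad = g.index[sample_call < CALL_RATE_MIN]
        report.samples_removed = list(bad)
        g = g.drop(index=bad)
    return g, meta, report


def find_cis_snvs(
    cpg_chromosome: str,
    cpg_position: int,
    snv_metadata: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> list[str]:
    """SNVs on the CpG's chromosome within +/- ``window`` bp (inclusive)."""
    meta = snv_metadata
    if "snv_id" in meta.columns:
        meta = meta.set_index("snv_id")
    same = meta["chromosome"].astype(str) == str(cpg_chromosome)
    near = (meta["position"] - cpg_position).abs() <= window
    return list(meta.index[same & near])


def ld_prune(genotypes: pd.DataFrame, p_threshold: float = 0.05) -> list[str]:
    """Greedy LD pruning by pairwise genotype correlation.

    SNVs are visited in MAF-descending order; a candidate is kept only
    when its Pearson correlation test against every already-kept SNV is
    non-significant (p >= ``p_threshold``). Returns the kept SNV ids.
    """
    if genotypes.shape[1] == 0:
        return []
    order = sorted(genotypes.columns, key=lambda s: -_maf(genotypes[s]))
    kept: list[str] = []
    for snv in order:
        x = genotypes[snv].to_numpy(float)
        independent = True
        for other in kept:
            y = genotypes[other].to_numpy(float)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                continue
            _, p = stats.pearsonr(x[mask], y[mask])
            if p < p_threshold:
                independent = False
                break
        if independent:
            kept.append(snv)
    return kept


def mqtl_test(beta_at_cpg: pd.Series, genotypes_at_snv: pd.Series) -> float:
    """Kruskal-Wallis test of methylation level across genotype classes.

    Tie-corrected H with (classes - 1) degrees of freedom; returns NaN
    when fewer than two genotype classes are present, and p = 1 when the
    beta values are identical in all classes.
    """
    df = pd.DataFrame({"beta": beta_at_cpg, "g": genotypes_at_snv}).dropna()
    classes = [grp["beta"].to_numpy() for _, grp in df.groupby("g")]
    if len(classes) < 2:
        return float("nan")
    if np.ptp(df["beta"].to_numpy()) < 1e-15:
        return 1.0
    return float(stats.kruskal(*classes).pvalue)


def adjusted_association(
    labels: pd.Series, beta_at_cpg: pd.Series, genotypes_at_snv: pd.Series
) -> dict:
    """Joint logistic model: severity ~ methylation + genotype.

    Reports Wald p-values for both predictors and whether the methylation
    association survives genotype adjustment at the p < 0.05 convention.
    A constant genotype column is dropped (reduces to the unadjusted
    model); separation falls back to a ridge-penalised fit, flagged.
    """
    from .dmp import _encode_labels, _ridge_logit

    df = pd.DataFrame(
        {"beta": beta_at_cpg, "g": genotypes_at_snv, "y": labels}
    ).dropna(subset=["beta", "y"])
    y = _encode_labels(df["y"])
    cols = [np.ones(len(df)), df["beta"].to_numpy(float)]
    genotype_used = df["g"].notna().all() and df["g"].nunique() > 1
    if genotype_used:
        cols.append(df["g"].to_numpy(float))
    X = np.column_stack(cols)
    flag = ""
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True) or np.any(np.isnan(fit.pvalues)):
            raise np.linalg.LinAlgError
        pvals = fit.pvalues
        coefs = fit.params
    except Exception:
        coefs, pvals = _ridge_logit(y.astype(float), X)
        flag = "separation"
    out = {
        "methylation_coef": float(coefs[1]),
        "methylation_p": float(pvals[1]),
        "genotype_p": float(pvals[2]) if genotype_used else float("nan"),
        "genotype_adjusted": bool(genotype_used),
        "methylation_survives_adjustment": bool(pvals[1] < 0.05),
        "flag": flag,
    }
    return out


def mqtl_scan(
    beta: pd.DataFrame,
    genotypes: pd.DataFrame,
    snv_metadata: pd.DataFrame,
    dmp_table: pd.DataFrame,
    labels: pd.Series | None = None,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Targeted mQTL scan around a table of (major) DMPs.

    For each DMP (rows with chromosome/position), candidate SNVs within
    the cis window are LD-pruned and tested with Kruskal-Wallis; when
    ``labels`` is given, each pair also gets the genotype-adjusted
    severity model. Returns a long table of CpG-SNV pairs.
    """
    rows = []
    for probe, row in dmp_table.iterrows():
        candidates = find_cis_snvs(
            row["chromosome"], int(row["position"]), snv_metadata, window
        )
        candidates = [c for c in candidates if c in genotypes.columns]
        if not candidates:
            continue
        for snv in ld_prune(genotypes[candidates]):
            p_kw = mqtl_test(beta.loc[probe], genotypes[snv])
            entry = {"probe_id": probe, "snv_id": snv, "kw_p": p_kw}
            if labels is not None:
                entry.update(
                    {
                        f"adj_{k}": v
                        for k, v in adjusted_association(
                            labels, beta.loc[probe], genotypes[snv]
                        ).items()
                    }
                )
            rows.append(entry)
    return pd.DataFrame(rows)
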