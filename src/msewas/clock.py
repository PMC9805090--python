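"""Epigenetic clocks and methylation age acceleration (MAA).

A clock is a linear predictor over a fixed set of "clock CpGs":
age = calibration(intercept + sum_i w_i * beta_i), with an optional
monotone linear calibration. Clock coefficient tables are pluggable
(TSV: cpg, weight, with the intercept carried separately), so any
published clock can be applied without bundling its coefficients. MAA is
the residual from regressing chronological age on the clock estimate;
mild/severe groups are compared with a t-test when the residuals pass
Shapiro-Wilk normality, a rank-sum test otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

MIN_CLOCK_COVERAGE = 0.9


@dataclass
class ClockModel:
    """Linear epigenetic clock with optional linear calibration.

    calibration maps the raw linear score s to years as
    ``calibration_scale * s + calibration_offset`` (identity by
    default); the scale must be positive so the map stays monotone.
    """

    weights: pd.Series  # indexed by clock CpG id
    intercept: float = 0.0
    calibration_scale: float = 1.0
    calibration_offset: float = 0.0
    name: str = "clock"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("clock weights must be finite")
        if self.calibration_scale <= 0:
            raise ValueError("calibration must be monotone (scale > 0)")

    @classmethod
    def from_table(cls, table: pd.DataFrame, **kwargs) -> "ClockModel":
        """Build from a two-column table (cpg, weight); rows with cpg
        '(Intercept)' set the intercept."""
        t = table.copy()
        inter = 0.0
        mask = t["cpg"] == "(Intercept)"
        if mask.any():
            inter = float(t.loc[mask, "weight"].iloc[0])
            t = t[~mask]
        return cls(weights=t.set_index("cpg")["weight"].astype(float),
                   intercept=inter, **kwargs)


@dataclass
class MaaResult:
    methylation_age: pd.Series
    maa: pd.Series  # residual years per sample
    slope: float
    intercept: float
    direction: str  # which variable was regressed on which


def clock_age(beta: pd.DataFrame, clock: ClockModel) -> pd.Series:
    """Apply a clock to a beta matrix; returns years per sample.

    At least 90% of the clock CpGs must be present in ``beta``; each
    missing clock CpG is imputed with the cohort-wide mean beta across
    the present clock CpGs (contributing weight x mean), and the
    imputation is logged.
    """
    present = clock.weights.index.intersection(beta.index)
    coverage = len(present) / len(clock.weights)
    if coverage < MIN_CLOCK_COVERAGE:
        raise ValueError(
            f"only {coverage:.0%} of clock CpGs present (need >= "
            f"{MIN_CLOCK_COVERAGE:.0%})"
        )
    score = beta.loc[present].T @ clock.weights.loc[present]
    missing = clock.weights.index.difference(beta.index)
    if len(missing):
        fill = beta.loc[present].to_numpy().mean()
        score = score + clock.weights.loc[missing].sum() * fill
        logger.info(
            "%s: imputed %d missing clock CpGs with cohort mean beta %.3f",
            clock.name, len(missing), fill,
        )
    raw = clock.intercept + score
    return clock.calibration_scale * raw + clock.calibration_offset


def compute_maa(
    chron_age: pd.Series,
    methyl_age: pd.Series,
    direction: str = "chronological_on_methylation",
) -> MaaResult:
    """Methylation age acceleration as regression residuals.

    The default regresses chronological age on the clock estimate and
    returns its residuals (positive = chronologically older than the
    regression line predicts from methylation). The conventional
    direction (methylation age on chronological age, positive = faster
    methylation ageing) is available via
    ``direction="methylation_on_chronological"``. Residuals sum to ~0
    over the cohort by construction.
    """
    idx = chron_age.index.intersection(methyl_age.index)
    if len(idx) < 3:
        raise ValueError("need >= 3 samples with both ages")
    x_map = {
        "chronological_on_methylation": (methyl_age, chron_age),
        "methylation_on_chronological": (chron_age, methyl_age),
    }
    if direction not in x_map:
        raise ValueError(f"unknown direction {direction!r}")
    x, y = (s.loc[idx].astype(float) for s in x_map[direction])
    if np.ptp(x.to_numpy()) < 1e-12:
        raise ValueError("regression predictor is constant")
    X = sm.add_constant(x.to_numpy())
    fit = sm.OLS(y.to_numpy(), X).fit()
    resid = pd.Series(fit.resid, index=idx, name="maa")
    return MaaResult(
        methylation_age=methyl_age.loc[idx],
        maa=resid,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        direction=direction,
    )


def _two_group_test(values: pd.Series, labels: pd.Series) -> dict:
    lab = pd.Series(labels).loc[values.index].astype(str).str.lower()
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    x = values[lab == groups[0]].to_numpy(float)
    y = values[lab == groups[1]].to_numpy(float)
    if min(len(x), len(y)) < 3:
        raise ValueError("need >= 3 samples per group")
    normal = (
        np.ptp(values.to_numpy()) > 0
        and stats.shapiro(values.to_numpy()).pvalue > 0.05
    )
    if np.ptp(np.concatenate([x, y])) < 1e-15:
        test, stat, p = "none", 0.0, 1.0
    elif normal:
        res = stats.ttest_ind(x, y)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.ranksums(x, y)
        test, stat, p = "ranksum", float(res.statistic), float(res.pvalue)
    return {
        "groups": groups,
        "test": test,
        "statistic": stat,
        "mean_diff": float(x.mean() - y.mean()),
        "p_value": p,
        "normality_p": float(stats.shapiro(values.to_numpy()).pvalue)
        if np.ptp(values.to_numpy()) > 0
        else float("nan"),
    }


def compare_maa(maa: pd.Series, labels: pd.Series) -> dict:
    """Shapiro-Wilk gated comparison of MAA between severity groups."""
    return _two_group_test(maa, labels)


def compare_smoking(dnam_packyears: pd.Series, labels: pd.Series) -> dict:
    """Compare DNA-methylation-estimated smoking pack-years between groups.

    Uses the same normality-gated strategy as MAA but prefers the
    rank-based branch, since pack-year estimates are typically skewed.
    """
    values = pd.Series(dnam_packyears, dtype=float)
    lab = pd.Series(labels).loc[values.index].astype(str).str.lower()
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    x = values[lab == groups[0]].to_numpy(float)
    y = values[lab == groups[1]].to_numpy(float)
    if np.ptp(np.concatenate([x, y])) < 1e-15:
        return {"groups": groups, "test": "none", "statistic": 0.0, "p_value": 1.0}
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {
        "groups": groups,
        "test": "mannwhitney",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_diff": float(x.mean() - y.mean()),
    }


def clock_dmp_overlap(clock: ClockModel, dmp_ids) -> list[str]:
    """Clock CpGs that also appear in a DMP list (exact set intersection)."""
    return sorted(set(clock.weights.index) & set(dmp_ids))
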