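"""Longitudinal ARMSS severity phenotyping.

The Age-Related MS Severity (ARMSS) score re-expresses an EDSS measurement
as a 0-10 rank relative to an age-matched reference population, so that
"EDSS 4 at age 30" scores as more severe than "EDSS 4 at age 65". A
patient's longitudinal ARMSS is the median of per-visit ARMSS scores over
their relapse-independent visits; cohort severity labels are assigned at
the 20th/80th percentile extremes of the longitudinal score distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PatientHistory

MIN_RELAPSE_INDEPENDENT_SCORES = 3
MIN_FOLLOW_UP_YEARS = 5.0


class EligibilityError(ValueError):
    """Raised when a patient history fails the cohort eligibility rules."""


class DegenerateCohortWarning(UserWarning):
    """Severity thresholds coincide; labels cannot separate the cohort."""


@dataclass
class ARMSSReference:
    """Empirical EDSS distributions per integer year of age.

    strata maps an integer age to a 1-D array of EDSS values observed at
    that age in a reference MS population. The ARMSS score of (age, EDSS)
    is 10 times the mid-rank fraction of the EDSS within its age stratum.
    """

    strata: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for age, values in self.strata.items():
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty reference stratum at age {age}")
            clean[int(age)] = arr
        self.strata = clean

    @property
    def age_range(self) -> tuple[int, int]:
        ages = sorted(self.strata)
        return ages[0], ages[-1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ARMSSReference":
        """Build from a long table with columns age, edss."""
        return cls(
            {int(a): sub["edss"].to_numpy(float) for a, sub in frame.groupby("age")}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, e) for a, vals in sorted(self.strata.items()) for e in vals]
        return pd.DataFrame(rows, columns=["age", "edss"])


@dataclass
class SeverityPhenotype:
    """Longitudinal ARMSS summary and severity label for one patient."""

    sample_id: str
    median_armss: float
    label: str  # mild / severe / excluded
    n_scores_used: int
    follow_up_years: float


def armss_score(age: float, edss: float, ref: ARMSSReference) -> float:
    """Age-relative severity of one EDSS measurement, on a 0-10 scale.

    The score is 10 x the mid-rank fraction of ``edss`` within the
    reference EDSS distribution at the (rounded) age: the mean of the
    fraction of reference values <= edss and the fraction < edss. It is
    monotone non-decreasing in EDSS at fixed age and invariant to
    duplicating the reference stratum.
    """
    age_bin = int(round(age))
    lo, hi = ref.age_range
    if age_bin not in ref.strata:
        raise ValueError(
            f"age {age:.1f} (bin {age_bin}) outside reference range [{lo}, {hi}]"
        )
    stratum = ref.strata[age_bin]
    frac_leq = np.mean(stratum <= edss)
    frac_lt = np.mean(stratum < edss)
    return float(10.0 * 0.5 * (frac_leq + frac_lt))


def check_eligibility(history: PatientHistory) -> list[str]:
    """Return the list of failed eligibility criteria (empty = eligible)."""
    failures = []
    n_ri = len(history.relapse_independent_visits)
    if n_ri < MIN_RELAPSE_INDEPENDENT_SCORES:
        failures.append(
            f"requires >= {MIN_RELAPSE_INDEPENDENT_SCORES} relapse-independent "
            f"EDSS scores, found {n_ri}"
        )
    if history.follow_up_years < MIN_FOLLOW_UP_YEARS:
        failures.append(
            f"requires >= {MIN_FOLLOW_UP_YEARS:g} years follow-up, "
            f"found {history.follow_up_years:.2f}"
        )
    return failures


def longitudinal_armss(
    history: PatientHistory, ref: ARMSSReference
) -> SeverityPhenotype:
    """Median ARMSS over a patient's relapse-independent visits.

    Relapse-associated visits are dropped before scoring. Histories with
    fewer than three relapse-independent EDSS scores or under five years
    of follow-up raise EligibilityError listing every failed criterion.
    The label field is left as "unlabelled"; cohort-level classification
    assigns mild/severe/excluded afterwards.
    """
    failures = check_eligibility(history)
    if failures:
        raise EligibilityError(
            f"{history.sample_id} ineligible: " + "; ".join(failures)
        )
    visits = history.relapse_independent_visits
    scores = [armss_score(v.age_at_visit, v.edss, ref) for v in visits]
    return SeverityPhenotype(
        sample_id=history.sample_id,
        median_armss=float(np.median(scores)),
        label="unlabelled",
        n_scores_used=len(scores),
        follow_up_years=history.follow_up_years,
    )


def classify_severity(
    medians, lower_pct: float = 20.0, upper_pct: float = 80.0
) -> pd.Series:
    """Label longitudinal ARMSS scores mild / severe / excluded.

    Scores at or below the cohort ``lower_pct`` percentile are mild and
    those at or above the ``upper_pct`` percentile severe (the "at or"
    rule keeps threshold ties). Percentiles use linear interpolation
    (type-7). If the two thresholds coincide, every score would qualify
    for both labels; all samples are then excluded with a warning.
    """
    medians = pd.Series(medians, dtype=float)
    if medians.empty:
        raise ValueError("no scores to classify")
    if len(medians) < 5:
        raise ValueError("need >= 5 scores for percentile-based classification")
    p_lo, p_hi = np.percentile(medians.to_numpy(), [lower_pct, upper_pct])
    if p_lo >= p_hi:
        warnings.warn(
            "severity thresholds degenerate (P20 >= P80); all samples excluded",
            DegenerateCohortWarning,
            stacklevel=2,
        )
        return pd.Series("excluded", index=medians.index)
    labels = pd.Series("excluded", index=medians.index)
    labels[medians <= p_lo] = "mild"
    labels[medians >= p_hi] = "severe"
    return labels


def _group_stats(values: np.ndarray) -> dict:
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "median": float(np.median(values)),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
        "n": int(values.size),
    }


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised mean difference with pooled SD; NaN when undefined."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        return float("nan")
    pooled = np.sqrt(
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def cohort_summary(phenotypes: pd.DataFrame, histories=None) -> pd.DataFrame:
    """Per-group summary statistics with Cohen's d between mild and severe.

    ``phenotypes`` needs columns sample_id, median_armss, label, plus any
    numeric covariates to summarise (age, follow-up years, ARR, ...).
    When ``histories`` is given, follow-up years and the number of EDSS
    scores are derived from the visit records.
    """
    df = phenotypes.copy()
    if histories is not None:
        fu = {h.sample_id: h.follow_up_years for h in histories}
        ne = {h.sample_id: len(h.relapse_independent_visits) for h in histories}
        df["follow_up_years"] = df["sample_id"].map(fu)
        df["n_edss_scores"] = df["sample_id"].map(ne)
    numeric = [
        c
        for c in df.columns
        if c not in ("sample_id", "label") and pd.api.types.is_numeric_dtype(df[c])
    ]
    rows = []
    mild = df[df["label"] == "mild"]
    severe = df[df["label"] == "severe"]
    for col in numeric:
        row: dict = {"characteristic": col}
        for name, grp in (("mild", mild), ("severe", severe), ("all", df)):
            vals = grp[col].dropna().to_numpy(float)
            if vals.size:
                for key, val in _group_stats(vals).items():
                    row[f"{name}_{key}"] = val
        row["cohens_d"] = cohens_d(
            mild[col].dropna().to_numpy(float), severe[col].dropna().to_numpy(float)
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("characteristic")
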