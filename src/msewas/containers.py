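"""Core data containers for the severity EWAS pipeline.

The pipeline's central array is a probes x samples matrix of methylation
beta values (the fraction of methylated signal at each CpG). Everything
downstream — filtering, normalisation, differential methylation, cell-type
deconvolution, clocks and classifiers — consumes either the beta view or
its logit2 ("M-value") view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import beta_to_m

CGI_CONTEXTS = ("island", "shore", "shelf", "opensea")

ANNOTATION_COLUMNS = (
    "probe_id",
    "chromosome",
    "position",
    "gene",
    "feature",
    "cgi_context",
    "non_cpg",
    "snp_related",
    "multi_hit",
    "autosomal",
)


@dataclass
class MethylationMatrix:
    """Probes x samples beta values with optional array QC channels.

    Parameters
    ----------
    beta : DataFrame
        Beta values in (0, 1); index = probe ids, columns = sample ids.
    design_type : Series, optional
        Per-probe Infinium assay design, "I" or "II".
    detection_p : DataFrame, optional
        Per-probe, per-sample detection p-values.
    bead_count : DataFrame, optional
        Per-probe, per-sample bead counts.
    """

    beta: pd.DataFrame
    design_type: pd.Series | None = None
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        arr = self.beta.to_numpy()
        if np.any(arr <= 0) or np.any(arr >= 1):
            # keep strict openness: clip once on construction
            from ._utils import clip_beta

            self.beta = clip_beta(self.beta)
        for name in ("detection_p", "bead_count"):
            aux = getattr(self, name)
            if aux is not None and not aux.index.equals(self.beta.index):
                raise ValueError(f"{name} index does not match beta index")

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def m(self) -> pd.DataFrame:
        """M-value view, log2(beta/(1-beta)); a pure function of beta."""
        return beta_to_m(self.beta)

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        idx = pd.Index(probe_ids)
        return MethylationMatrix(
            beta=self.beta.loc[idx],
            design_type=None if self.design_type is None else self.design_type.loc[idx],
            detection_p=None if self.detection_p is None else self.detection_p.loc[idx],
            bead_count=None if self.bead_count is None else self.bead_count.loc[idx],
        )

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        cols = pd.Index(sample_ids)
        return MethylationMatrix(
            beta=self.beta[cols],
            design_type=self.design_type,
            detection_p=None if self.detection_p is None else self.detection_p[cols],
            bead_count=None if self.bead_count is None else self.bead_count[cols],
        )


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a probe annotation table and return it indexed by probe_id.

    Required columns: chromosome, position (1-based), gene, feature,
    cgi_context plus boolean flags non_cpg, snp_related, multi_hit,
    autosomal. Positions must be positive and cgi_context one of
    island/shore/shelf/opensea.
    """
    ann = ann.copy()
    if "probe_id" in ann.columns:
        ann = ann.set_index("probe_id")
    missing = [c for c in ANNOTATION_COLUMNS[1:] if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if (ann["position"] <= 0).any():
        raise ValueError("annotation positions must be positive (1-based)")
    bad = set(ann["cgi_context"].unique()) - set(CGI_CONTEXTS)
    if bad:
        raise ValueError(f"unknown CGI context values: {sorted(bad)}")
    return ann


@dataclass
class VisitRecord:
    """One clinical visit: age, EDSS and whether the score is relapse-independent."""

    age_at_visit: float
    edss: float
    relapse_independent: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.edss <= 10.0:
            raise ValueError(f"EDSS must be in [0, 10], got {self.edss}")
        if self.age_at_visit <= 0:
            raise ValueError("age_at_visit must be positive")


@dataclass
class PatientHistory:
    """Visit-level EDSS records for one patient."""

    sample_id: str
    visits: list[VisitRecord] = field(default_factory=list)

    @property
    def relapse_independent_visits(self) -> list[VisitRecord]:
        return [v for v in self.visits if v.relapse_independent]

    @property
    def follow_up_years(self) -> float:
        if not self.visits:
            return 0.0
        ages = [v.age_at_visit for v in self.visits]
        return max(ages) - min(ages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "age_at_visit": [v.age_at_visit for v in self.visits],
                "edss": [v.edss for v in self.visits],
                "relapse_independent": [v.relapse_independent for v in self.visits],
            }
        )


def histories_to_frame(histories) -> pd.DataFrame:
    """Stack patient histories into a long visit table (one row per visit)."""
    return pd.concat([h.to_frame() for h in histories], ignore_index=True)


def frame_to_histories(visits: pd.DataFrame) -> list[PatientHistory]:
    """Inverse of histories_to_frame: build PatientHistory objects per sample."""
    out = []
    for sid, sub in visits.groupby("sample_id", sort=False):
        out.append(
            PatientHistory(
                sample_id=str(sid),
                visits=[
                    VisitRecord(r.age_at_visit, r.edss, bool(r.relapse_independent))
                    for r in sub.itertuples()
                ],
            )
        )
    return out
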