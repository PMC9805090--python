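"""Proximity/direction DMR calling.

Kernel-based region finders can miss regions when effect sizes are
small; this module implements the simple chaining rule instead: a DMR is
a maximal run of at least ``min_cpgs`` differentially methylated
positions on one chromosome, all with the same direction of effect, each
within ``max_gap`` bp of the adjacent one, and each passing a stringent
FDR cut (default 0.01). Width follows the end - start convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DMR_FDR_MAX = 0.01
DMR_MAX_GAP = 1000
DMR_MIN_CPGS = 2


@dataclass
class DmrResult:
    """One called region; member positions are 1-based inclusive."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_cpgs: int
    max_delta: float  # signed delta of the largest-|delta| member
    mean_delta: float
    member_probes: list[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end_bp - self.start_bp


def call_dmrs(
    dmps: pd.DataFrame,
    max_gap: int = DMR_MAX_GAP,
    min_cpgs: int = DMR_MIN_CPGS,
    fdr_max: float = DMR_FDR_MAX,
) -> list[DmrResult]:
    """Chain nearby same-direction DMPs into regions.

    ``dmps`` must carry columns chromosome, position, delta_meth and fdr
    (index = probe id). DMPs at or above ``fdr_max`` are discarded; the
    survivors are sorted by (chromosome, position) and maximal runs are
    chained where each adjacent gap is <= ``max_gap`` bp and the signs of
    delta_meth match. A sign flip splits the run at the flip. Runs with
    at least ``min_cpgs`` members are emitted; region bounds are the
    first/last member positions. Duplicate positions on one chromosome
    raise ValueError; output is invariant to input row order.
    """
    required = {"chromosome", "position", "delta_meth", "fdr"}
    missing = required - set(dmps.columns)
    if missing:
        raise ValueError(f"dmps table missing columns: {sorted(missing)}")
    passing = dmps[dmps["fdr"] < fdr_max].copy()
    regions: list[DmrResult] = []
    for chrom, sub in passing.groupby("chromosome", sort=True):
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        if len(np.unique(positions)) != len(positions):
            raise ValueError(f"duplicate probe positions on chromosome {chrom}")
        deltas = sub["delta_meth"].to_numpy()
        probes = list(sub.index)
        run = [0]
        for i in range(1, len(sub)):
            gap_ok = positions[i] - positions[i - 1] <= max_gap
            sign_ok = np.sign(deltas[i]) == np.sign(deltas[i - 1])
            if gap_ok and sign_ok:
                run.append(i)
            else:
                _emit(regions, chrom, run, positions, deltas, probes, min_cpgs)
                run = [i]
        _emit(regions, chrom, run, positions, deltas, probes, min_cpgs)
    return regions


def _emit(regions, chrom, run, positions, deltas, probes, min_cpgs) -> None:
    if len(run) < min_cpgs:
        return
    d = deltas[run]
    regions.append(
        DmrResult(
            chromosome=str(chrom),
            start_bp=int(positions[run[0]]),
            end_bp=int(positions[run[-1]]),
            n_cpgs=len(run),
            max_delta=float(d[np.argmax(np.abs(d))]),
            mean_delta=float(d.mean()),
            member_probes=[probes[i] for i in run],
        )
    )


def dmrs_to_frame(regions: list[DmrResult]) -> pd.DataFrame:
    """Tabular view with both 1-based inclusive and BED (0-based
    half-open) coordinates."""
    rows = []
    for r in regions:
        rows.append(
            {
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "width": r.width,
                "n_cpgs": r.n_cpgs,
                "max_delta": r.max_delta,
                "mean_delta": r.mean_delta,
                "member_probes": ",".join(r.member_probes),
                "bed_start": r.start_bp - 1,
                "bed_end": r.end_bp,
            }
        )
    return pd.DataFrame(rows)
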