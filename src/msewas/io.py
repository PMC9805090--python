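"""Readers/writers for the pipeline's tabular interchange formats.

Everything is plain text: beta matrices as TSV (probes as rows), sample
sheets and probe annotation as CSV, genotypes as VCF (GT field) or a
0/1/2-coded TSV, clock coefficient tables as TSV and planted truth as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clock import ClockModel


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def read_beta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_annotation_csv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False)


def read_annotation_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"chromosome": str}, keep_default_na=False, na_values=[]
    )


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="sample_id")


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(
    genotypes: pd.DataFrame, metadata: pd.DataFrame, path
) -> None:
    """Write allele counts as a minimal VCFv4.2 with GT genotypes.

    ``genotypes`` is samples x SNVs ({0,1,2}, NaN = missing), metadata is
    indexed by SNV id with chromosome/position/ref/alt columns. Records
    are emitted in (chromosome, position) order.
    """
    meta = metadata.copy()
    if "snv_id" in meta.columns:
        meta = meta.set_index("snv_id")
    samples = list(genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    order = meta.sort_values(["chromosome", "position"]).index
    for snv in order:
        row = meta.loc[snv]
        calls = [
            "./."
            if pd.isna(g)
            else _GT_CODES[int(g)]
            for g in genotypes[snv]
        ]
        lines.append(
            f"{row['chromosome']}\t{int(row['position'])}\t{snv}\t"
            f"{row.get('ref', 'A')}\t{row.get('alt', 'G')}\t.\tPASS\t.\tGT\t"
            + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read GT genotypes from a VCF into (samples x SNVs counts, metadata)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    counts = {}
    rows = []
    for variant in vcf:
        snv_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        gts = []
        for g in variant.genotypes:
            alleles = [a for a in g[:-1] if a >= 0]
            gts.append(sum(alleles) if alleles else np.nan)
        counts[snv_id] = gts
        rows.append(
            {
                "snv_id": snv_id,
                "chromosome": str(variant.CHROM),
                "position": int(variant.POS),
                "ref": variant.REF,
                "alt": variant.ALT[0] if variant.ALT else ".",
            }
        )
    genotypes = pd.DataFrame(counts, index=samples)
    metadata = pd.DataFrame(rows).set_index("snv_id")
    return genotypes, metadata


def write_clock_tsv(clock: ClockModel, path) -> None:
    rows = [("(Intercept)", clock.intercept)]
    rows += list(clock.weights.items())
    pd.DataFrame(rows, columns=["cpg", "weight"]).to_csv(path, sep="\t", index=False)


def read_clock_tsv(path, **kwargs) -> ClockModel:
    return ClockModel.from_table(pd.read_csv(path, sep="\t"), **kwargs)


def write_truth_json(truth: dict, path) -> None:
    """Serialise the generator's planted truth to JSON."""

    def convert(obj):
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="index")
        if isinstance(obj, ClockModel):
            return {
                "weights": obj.weights.to_dict(),
                "intercept": obj.intercept,
                "calibration_scale": obj.calibration_scale,
                "calibration_offset": obj.calibration_offset,
            }
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (list, tuple)):
            return [convert(x) for x in obj]
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(json.dumps(convert(truth), indent=1))


def write_cohort(cohort, out_dir) -> dict:
    """Write a SyntheticCohort's files into ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .containers import histories_to_frame

    paths = {
        "beta": out / "beta.tsv",
        "annotation": out / "annotation.csv",
        "sample_sheet": out / "sample_sheet.csv",
        "visits": out / "visits.csv",
        "genotypes_vcf": out / "genotypes.vcf",
        "cell_reference": out / "cell_reference.tsv",
        "truth": out / "truth.json",
    }
    write_beta_tsv(cohort.beta.beta, paths["beta"])
    write_annotation_csv(cohort.annotation, paths["annotation"])
    cohort.sample_sheet.to_csv(paths["sample_sheet"], index=False)
    histories_to_frame(cohort.histories).to_csv(paths["visits"], index=False)
    write_genotypes_vcf(cohort.genotypes, cohort.snv_metadata, paths["genotypes_vcf"])
    cohort.cell_reference.to_csv(paths["cell_reference"], sep="\t", index_label="probe_id")
    write_truth_json(cohort.truth, paths["truth"])
    return paths
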