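"""Targeted mQTL analysis: genotype QC, cis windows, LD pruning,
Kruskal-Wallis tests and genotype-adjusted severity models.

For each planted CpG-SNV pair, SNVs within +/- 5 kb are LD-pruned and
tested for association between genotype and methylation; a joint
logistic model then asks whether the methylation-severity association
survives genotype adjustment.
"""

from msewas import SimulationConfig, genotype_qc, simulate_cohort
from msewas.mqtl import mqtl_scan

cfg = SimulationConfig(
    n_samples=200, n_probes=1500, n_truth_dmps=30,
    effect_sizes=(0.06, 0.10), n_mqtl_pairs=6, n_null_snvs=20,
    mqtl_effect=0.5, seed=31,
)
cohort = simulate_cohort(cfg)

genotypes, metadata, report = genotype_qc(cohort.genotypes, cohort.snv_metadata)
print(f"genotype QC: {report.total_snvs_removed} SNVs removed "
      f"(call rate {report.call_rate}, MAF {report.maf}, HWE {report.hwe}, "
      f"monomorphic {report.monomorphic}, non-autosomal {report.non_autosomal}); "
      f"{len(report.samples_removed)} samples removed")

# scan around the planted mQTL CpGs
positions = cohort.annotation.set_index("probe_id")[["chromosome", "position"]]
targets = positions.loc[[cpg for cpg, _ in cohort.truth["mqtl_pairs"]]]
table = mqtl_scan(
    cohort.beta.beta, genotypes, metadata, targets,
    labels=cohort.group, window=5000,
)
print(f"\ncis pairs tested after LD pruning: {len(table)}")
planted = {pair for pair in cohort.truth["mqtl_pairs"]}
for _, row in table.iterrows():
    tag = "planted" if (row.probe_id, row.snv_id) in planted else "null"
    print(f"  {row.probe_id} x {row.snv_id}: KW p = {row.kw_p:.2e} [{tag}] "
          f"methylation survives genotype adjustment: {row.adj_methylation_survives_adjustment}")

# Planted pairs show Kruskal-Wallis p far below 1e-4 while bystander
# SNVs in the window do not; the severity association at planted DMPs
# is not explained away by genotype, mirroring a methylation signal
# that is genetically influenced but not genetically determined.
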