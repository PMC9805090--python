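"""Cell-type deconvolution and cell-specific differential methylation.

Whole-blood beta values are decomposed against six leukocyte reference
profiles by constrained least squares; group differences in proportions
are tested per type, and a proportion x severity interaction model
scans for cell-specific DMPs at the genome-wide threshold p <= 9e-8.
"""

from msewas import (
    SimulationConfig,
    cell_specific_dmps,
    compare_proportions,
    estimate_proportions,
    simulate_cohort,
)
from msewas._utils import beta_to_m
from msewas.deconvolution import select_marker_probes

cfg = SimulationConfig(
    n_samples=200, n_probes=1500, n_truth_dmps=0,
    cell_specific_effects=True, n_cs_dmps=8, cs_cell_type="CD8T",
    cs_effect=0.35, noise_sd=0.15, seed=29,
)
cohort = simulate_cohort(cfg)

markers = select_marker_probes(cohort.cell_reference, per_type=80)
props = estimate_proportions(
    cohort.beta.beta.loc[markers], cohort.cell_reference.loc[markers]
)
mae = (props - cohort.truth["proportions"]).abs().mean().mean()
print(f"proportion recovery MAE vs truth: {mae:.3f}")
print("mean estimated proportions:")
print(props.mean().round(3).to_string())

table = compare_proportions(props, cohort.group)
print("\ngroup comparison per type (none should differ here):")
print(table[["test", "p_value", "fdr"]].round(3).to_string())

m_values = beta_to_m(cohort.beta.beta.loc[cohort.truth["cs_dmps"]])
stats = cell_specific_dmps(m_values, props, cohort.group)
sig = stats[stats["significant"]]
print(f"\ncsDMP calls at the planted probes: {len(sig)}")
print(sig.groupby("cell_type").size().to_string())

# The planted CD8 T-cell effect surfaces as CD8 interaction hits; other
# cell types stay quiet, mirroring how interaction models attribute a
# whole-blood signal to the cell type that carries it.
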