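"""Synthetic cohort generator with planted ground truth.

Because the real methylation and clinical data this pipeline is designed
for are access-controlled, the generator is the canonical input source:
it produces cohorts carrying every statistical structure the downstream
stages assume — two severity groups with planted DMP effects, leukocyte
mixture structure over six cell types, cis-mQTL additive genotype
effects, age-linear clock CpGs, optional batch shifts, and visit-level
EDSS trajectories satisfying the cohort eligibility rules — together
with machine-readable truth for parameter-recovery tests.

Construction order per probe/sample: cell-type reference profiles are
mixed with Dirichlet weights, severity effects are added on the beta
scale, the matrix moves to the M (logit2) scale where mQTL, batch
location/scale and Gaussian noise apply, and the result maps back to
beta — noise on the logit scale keeps beta inside (0, 1) without
truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import beta_to_m, clip_beta, m_to_beta
from .clock import ClockModel
from .containers import MethylationMatrix, PatientHistory, VisitRecord
from .deconvolution import CELL_TYPES
from .phenotyping import ARMSSReference


class ConfigError(ValueError):
    """A SimulationConfig field violates its invariant."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the study conditions at desk scale: a 235-sample
    cohort split 119 mild / 116 severe, severity effects spanning the
    1-15% beta range, six leukocyte types with granulocyte-dominated
    blood mixtures, and a two-level chip batch with no shift (batch
    effects are opt-in so the default cohort is clean). The probe count
    is a scaled-down stand-in for a full array.
    """

    n_samples: int = 235
    n_probes: int = 20000
    n_truth_dmps: int = 50
    effect_sizes: tuple = (0.01, 0.02, 0.05, 0.10, 0.14)
    n_truth_dmrs: int = 2
    n_cell_types: int = 6
    dirichlet_concentration: tuple = (6.0, 4.0, 3.0, 2.0, 3.0, 12.0)
    marker_probes_per_type: int = 100
    cell_specific_effects: bool = False
    n_cs_dmps: int = 10
    cs_cell_type: str = "CD8T"
    cs_effect: float = 0.15
    n_mqtl_pairs: int = 10
    n_null_snvs: int = 30
    mqtl_effect: float = 0.5  # delta M per alternate allele
    n_clock_cpgs: int = 30
    maa_shift_years: float = 1.36  # biological-age offset of the severe group
    batch_labels: tuple | None = None  # per-sample; round-robin over 2 if None
    n_batches: int = 2
    batch_shift: float = 0.0  # delta M per batch step
    batch_scale: float = 1.0  # per-batch step multiplier on centred M
    noise_sd: float = 0.3  # M-value scale (~0.05 on beta at mid-methylation)
    type1_fraction: float = 0.2
    mild_fraction: float = 119.0 / 235.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_truth_dmps > self.n_probes:
            raise ConfigError("n_truth_dmps exceeds n_probes")
        if any(not 0 <= e <= 0.15 for e in self.effect_sizes):
            raise ConfigError("effect_sizes must lie in [0, 0.15]")
        if len(self.dirichlet_concentration) != self.n_cell_types:
            raise ConfigError(
                "dirichlet_concentration length must equal n_cell_types"
            )
        if any(c <= 0 for c in self.dirichlet_concentration):
            raise ConfigError("dirichlet_concentration entries must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.batch_labels is not None and len(self.batch_labels) != self.n_samples:
            raise ConfigError("batch_labels must give one label per sample")
        if not 0 < self.mild_fraction < 1:
            raise ConfigError("mild_fraction must lie in (0, 1)")
        if self.n_cell_types != len(CELL_TYPES):
            # the generator names types after the six standard leukocytes
            if self.n_cell_types > len(CELL_TYPES):
                raise ConfigError("n_cell_types must be <= 6")

    @property
    def cell_types(self) -> tuple:
        return CELL_TYPES[: self.n_cell_types]


@dataclass
class SyntheticCohort:
    beta: MethylationMatrix
    annotation: pd.DataFrame
    sample_sheet: pd.DataFrame
    histories: list[PatientHistory]
    genotypes: pd.DataFrame  # samples x SNVs, allele counts
    snv_metadata: pd.DataFrame
    cell_reference: pd.DataFrame
    armss_reference: ARMSSReference
    truth: dict = field(default_factory=dict)

    @property
    def group(self) -> pd.Series:
        return self.sample_sheet.set_index("sample_id")["group"]


def make_armss_reference(seed: int = 0, per_age: int = 300) -> ARMSSReference:
    """Synthetic EDSS-by-age reference population.

    Per integer age 18-80, EDSS values are drawn from a gamma
    distribution whose mean rises with age (disability accrues over the
    disease course) and rounded to the 0.5-step EDSS grid.
    """
    rng = np.random.default_rng(seed)
    strata = {}
    for age in range(18, 81):
        mean = min(6.5, 0.5 + 0.09 * (age - 18))
        draws = rng.gamma(shape=2.0, scale=mean / 2.0, size=per_age)
        edss = np.clip(np.round(draws * 2) / 2, 0, 10)
        strata[age] = edss
    return ARMSSReference(strata)


def _reference_quantile_edss(ref: ARMSSReference, age: float, q: float) -> float:
    stratum = np.sort(ref.strata[int(round(np.clip(age, *ref.age_range)))])
    val = np.quantile(stratum, q)
    return float(np.clip(np.round(val * 2) / 2, 0, 10))


def simulate_histories(
    config: SimulationConfig,
    group_labels,
    ages_at_blood=None,
    ref: ARMSSReference | None = None,
) -> list[PatientHistory]:
    """Visit-level EDSS trajectories consistent with the severity labels.

    Every history satisfies the eligibility rules by construction
    (follow-up span >= 5 years, >= 3 relapse-independent EDSS scores).
    Severe-group trajectories track a high EDSS-for-age quantile of the
    reference population and mild-group a low one, so longitudinal ARMSS
    separates the groups.
    """
    config.validate()
    group_labels = list(group_labels)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    if ref is None:
        ref = make_armss_reference(config.seed)
    if ages_at_blood is None:
        ages_at_blood = rng.uniform(30, 72, size=len(group_labels))
    histories = []
    for i, label in enumerate(group_labels):
        age_blood = float(ages_at_blood[i])
        span = float(np.clip(5.0 + rng.exponential(5.0), 5.0, 25.0))
        first_age = max(19.0, age_blood - span)
        span = age_blood - first_age if age_blood - first_age >= 5 else span
        last_age = max(age_blood, first_age + 5.0)
        n_visits = int(rng.integers(6, 18))
        ages = np.sort(rng.uniform(first_age, last_age, size=n_visits - 2))
        ages = np.concatenate([[first_age], ages, [last_age]])
        q = rng.uniform(0.02, 0.18) if label == "mild" else rng.uniform(0.82, 0.98)
        visits = []
        for j, a in enumerate(ages):
            edss = _reference_quantile_edss(ref, a, q)
            jitter = rng.choice([-0.5, 0.0, 0.0, 0.5])
            edss = float(np.clip(edss + jitter, 0, 10))
            independent = bool(j < 3 or rng.random() > 0.1)
            visits.append(VisitRecord(float(a), edss, independent))
        histories.append(PatientHistory(sample_id=f"S{i:04d}", visits=visits))
    return histories


def inject_mqtl(
    beta: pd.DataFrame, genotypes: pd.DataFrame, pairs, effect: float
) -> pd.DataFrame:
    """Shift methylation at CpGs by ``effect`` M-units per alternate allele.

    ``pairs`` is an iterable of (cpg_id, snv_id); other probes are left
    untouched. Unknown ids raise KeyError.
    """
    out_m = beta_to_m(beta)
    for cpg, snv in pairs:
        if cpg not in beta.index:
            raise KeyError(f"unknown CpG id {cpg!r}")
        if snv not in genotypes.columns:
            raise KeyError(f"unknown SNV id {snv!r}")
        g = genotypes[snv].loc[beta.columns].to_numpy(float)
        out_m.loc[cpg] = out_m.loc[cpg] + effect * g
    return clip_beta(m_to_beta(out_m))


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic severity cohort (deterministic per seed)."""
    config = config or SimulationConfig()
    config.validate()
    root = np.random.SeedSequence([config.seed, 1])
    rng = np.random.default_rng(root)

    n, p = config.n_samples, config.n_probes
    samples = [f"S{i:04d}" for i in range(n)]
    probes = [f"cg{i:07d}" for i in range(p)]
    n_mild = int(round(config.mild_fraction * n))
    groups = np.array(["mild"] * n_mild + ["severe"] * (n - n_mild))

    # --- probe annotation -------------------------------------------------
    chromosomes = rng.integers(1, 23, size=p).astype(str)
    positions = np.empty(p, dtype=int)
    for chrom in np.unique(chromosomes):
        idx = np.flatnonzero(chromosomes == chrom)
        # spacing >= 2 kb prevents accidental proximity clusters
        gaps = rng.integers(2000, 50000, size=len(idx))
        positions[idx] = 10_000 + np.cumsum(gaps)
    cgi = rng.choice(
        ["opensea", "shore", "shelf", "island"], size=p, p=[0.70, 0.18, 0.07, 0.05]
    )
    feature = rng.choice(
        ["IGR", "body", "TSS200", "TSS1500", "3'UTR"], size=p,
        p=[0.45, 0.3, 0.08, 0.1, 0.07],
    )
    gene = np.where(
        feature == "IGR", "", np.array([f"GENE{i % 997}" for i in range(p)])
    )
    annotation = pd.DataFrame(
        {
            "probe_id": probes,
            "chromosome": chromosomes,
            "position": positions,
            "gene": gene,
            "feature": feature,
            "cgi_context": cgi,
            "non_cpg": False,
            "snp_related": False,
            "multi_hit": False,
            "autosomal": True,
        }
    )

    # --- cell-type reference profiles ------------------------------------
    kind = rng.choice([0, 1, 2], size=p, p=[0.45, 0.45, 0.10])
    mu = np.where(
        kind == 0,
        rng.beta(2, 18, size=p),
        np.where(kind == 1, rng.beta(18, 2, size=p), rng.beta(5, 5, size=p)),
    )
    types = config.cell_types
    K = len(types)
    reference = np.tile(mu[:, None], (1, K))
    marker_ids: dict[str, np.ndarray] = {}
    cursor = 0
    marker_pool = rng.permutation(p)
    # cap marker usage so at most half the array is cell-type markers
    per_type = min(config.marker_probes_per_type, p // (2 * K))
    for k, ct in enumerate(types):
        sel = marker_pool[cursor : cursor + per_type]
        cursor += per_type
        # flip the marker probes for this type toward the opposite mode
        reference[sel, k] = np.where(mu[sel] < 0.5,
                                     rng.uniform(0.75, 0.95, len(sel)),
                                     rng.uniform(0.05, 0.25, len(sel)))
        marker_ids[ct] = sel
    reference_df = pd.DataFrame(reference, index=probes, columns=types)

    weights = rng.dirichlet(config.dirichlet_concentration, size=n)  # n x K
    mixed = reference @ weights.T  # p x n

    # --- planted severity effects (whole-blood mean shifts) ---------------
    eligible = np.flatnonzero(
        (mixed.mean(axis=1) > 0.15)
        & (mixed.mean(axis=1) < 0.85)
        & ~np.isin(np.arange(p), marker_pool[:cursor])
    )
    if len(eligible) < config.n_truth_dmps:
        raise ConfigError(
            f"n_truth_dmps={config.n_truth_dmps} exceeds the eligible "
            f"mid-range non-marker probe pool ({len(eligible)}); increase "
            "n_probes or reduce planted structure"
        )
    picked = rng.choice(eligible, size=config.n_truth_dmps, replace=False)
    effects = np.array(
        [config.effect_sizes[i % len(config.effect_sizes)] for i in range(len(picked))]
    )
    signs = rng.choice([-1.0, 1.0], size=len(picked))
    severe_mask = groups == "severe"
    dmp_effects = pd.Series(effects * signs, index=[probes[i] for i in picked])
    for idx, eff in zip(picked, effects * signs):
        mixed[idx, severe_mask] = np.clip(
            mixed[idx, severe_mask] + eff, 0.02, 0.98
        )

    # --- planted DMR clusters: relocate pairs of truth DMPs side by side --
    dmr_truth = []
    strong = np.argsort(-np.abs(dmp_effects.to_numpy()))
    for r in range(min(config.n_truth_dmrs, len(picked) // 2)):
        a, b = picked[strong[2 * r]], picked[strong[2 * r + 1]]
        chrom = annotation.loc[a, "chromosome"]
        pos_a = int(annotation.loc[a, "position"])
        pos_b = pos_a + int(rng.integers(150, 800))
        annotation.loc[b, ["chromosome", "position"]] = [chrom, pos_b]
        # force matching sign on the second member
        eff_a = dmp_effects.iloc[strong[2 * r]]
        eff_b = dmp_effects.iloc[strong[2 * r + 1]]
        if np.sign(eff_a) != np.sign(eff_b):
            delta = -2 * eff_b
            dmp_effects.iloc[strong[2 * r + 1]] = -eff_b
            mixed[b, severe_mask] = np.clip(mixed[b, severe_mask] + delta, 0.02, 0.98)
        dmr_truth.append(
            {
                "chromosome": str(chrom),
                "start_bp": min(pos_a, pos_b),
                "end_bp": max(pos_a, pos_b),
                "member_probes": [probes[a], probes[b]],
            }
        )

    # --- optional cell-specific effects (interaction structure) ----------
    cs_ids: list[str] = []
    if config.cell_specific_effects:
        k = types.index(config.cs_cell_type)
        pool = [i for i in eligible if probes[i] not in dmp_effects.index]
        cs_sel = rng.choice(pool, size=config.n_cs_dmps, replace=False)
        for idx in cs_sel:
            mixed[idx, severe_mask] = np.clip(
                mixed[idx, severe_mask]
                + config.cs_effect * weights[severe_mask, k],
                0.02,
                0.98,
            )
        cs_ids = [probes[i] for i in cs_sel]

    # --- ages, clinical covariates ----------------------------------------
    age_blood = rng.uniform(30, 72, size=n)
    aao_base = np.where(severe_mask, 33.0, 28.0)
    age_onset = np.clip(rng.normal(aao_base, 6.0), 16.0, age_blood - 6.0)
    symptom_site = ["optic", "supratentorial", "brainstem", "spinal"]
    site_probs = {"mild": [0.35, 0.3, 0.2, 0.15], "severe": [0.25, 0.3, 0.2, 0.25]}
    sites = np.array(
        [rng.choice(symptom_site, p=site_probs[g]) for g in groups]
    )
    arr = np.where(severe_mask, rng.exponential(0.2, n), rng.exponential(0.12, n))

    # --- clock CpGs --------------------------------------------------------
    marker_set = set(marker_pool[:cursor].tolist())
    planted = set(dmp_effects.index) | set(cs_ids)
    clock_pool = [
        i for i in range(p) if probes[i] not in planted and i not in marker_set
    ]
    clock_sel = rng.choice(clock_pool, size=config.n_clock_cpgs, replace=False)
    slopes = rng.choice([-1, 1], config.n_clock_cpgs) * rng.uniform(
        0.003, 0.006, config.n_clock_cpgs
    )
    mu50 = rng.uniform(0.35, 0.65, config.n_clock_cpgs)
    bio_age = age_blood + np.where(severe_mask, config.maa_shift_years, 0.0)
    for j, idx in enumerate(clock_sel):
        mixed[idx, :] = np.clip(mu50[j] + slopes[j] * (bio_age - 50.0), 0.02, 0.98)
    clock_ids = [probes[i] for i in clock_sel]
    w = 1.0 / (config.n_clock_cpgs * slopes)
    clock_model = ClockModel(
        weights=pd.Series(w, index=clock_ids),
        intercept=float(50.0 - np.sum(mu50 * w)),
        name="synthetic-clock",
    )

    # --- genotypes and cis-mQTL pairs -------------------------------------
    # mQTLs target severity DMPs first (the targeted design tests genotype
    # at differentially methylated loci), sparing DMR-cluster members so
    # genotype variance cannot mask the planted region signal
    dmr_members = {pid for r in dmr_truth for pid in r["member_probes"]}
    excluded = set(clock_ids) | set(cs_ids) | dmr_members
    priority = [i for i in picked if probes[i] not in excluded]
    backfill = [
        i for i in eligible
        if probes[i] not in excluded and i not in set(priority)
    ]
    pool = priority + list(rng.permutation(backfill))
    mqtl_cpgs = np.array(pool[: config.n_mqtl_pairs], dtype=int)
    if len(mqtl_cpgs) < config.n_mqtl_pairs:
        raise ConfigError("n_mqtl_pairs exceeds available probes")
    snv_rows = []
    geno_cols = {}
    pairs = []
    for j, idx in enumerate(mqtl_cpgs):
        snv_id = f"rs{j:06d}"
        maf = rng.uniform(0.2, 0.5)
        geno_cols[snv_id] = rng.binomial(2, maf, size=n)
        snv_rows.append(
            {
                "snv_id": snv_id,
                "chromosome": str(annotation.loc[idx, "chromosome"]),
                "position": int(annotation.loc[idx, "position"])
                + int(rng.integers(-4000, 4000)),
                "ref": "A",
                "alt": "G",
            }
        )
        pairs.append((probes[idx], snv_id))
    for j in range(config.n_null_snvs):
        snv_id = f"rs9{j:05d}"
        maf = rng.uniform(0.1, 0.5)
        geno_cols[snv_id] = rng.binomial(2, maf, size=n)
        anchor = int(rng.integers(0, p))
        snv_rows.append(
            {
                "snv_id": snv_id,
                "chromosome": str(annotation.loc[anchor, "chromosome"]),
                "position": int(annotation.loc[anchor, "position"])
                + int(rng.integers(-4500, 4500)),
                "ref": "C",
                "alt": "T",
            }
        )
    genotypes = pd.DataFrame(geno_cols, index=samples)
    snv_metadata = pd.DataFrame(
        snv_rows, columns=["snv_id", "chromosome", "position", "ref", "alt"]
    ).set_index("snv_id")

    # --- assemble on the M scale ------------------------------------------
    mvals = beta_to_m(pd.DataFrame(mixed, index=probes, columns=samples))
    for (cpg, snv) in pairs:
        mvals.loc[cpg] += config.mqtl_effect * genotypes[snv].to_numpy(float)

    if config.batch_labels is not None:
        batch = pd.Series(list(config.batch_labels), index=samples)
    else:
        batch = pd.Series(
            [f"B{i % config.n_batches + 1}" for i in range(n)], index=samples
        )
    batch_levels = {b: i for i, b in enumerate(pd.unique(batch))}
    if config.batch_shift != 0.0 or config.batch_scale != 1.0:
        centre = mvals.mean(axis=1)
        for s in samples:
            step = batch_levels[batch[s]]
            shift = config.batch_shift * step
            scale = config.batch_scale**step
            mvals[s] = centre + (mvals[s] - centre) * scale + shift

    if config.noise_sd > 0:
        mvals = mvals + rng.normal(0.0, config.noise_sd, size=mvals.shape)
    beta = clip_beta(m_to_beta(mvals))

    design_type = pd.Series(
        np.where(rng.random(p) < config.type1_fraction, "I", "II"), index=probes
    )
    detection_p = pd.DataFrame(
        rng.uniform(0, 0.005, size=(p, n)), index=probes, columns=samples
    )
    bead_count = pd.DataFrame(
        rng.integers(5, 30, size=(p, n)), index=probes, columns=samples
    )
    matrix = MethylationMatrix(
        beta=beta, design_type=design_type,
        detection_p=detection_p, bead_count=bead_count,
    )

    # --- histories and sample sheet ---------------------------------------
    armss_ref = make_armss_reference(config.seed)
    histories = simulate_histories(config, groups, ages_at_blood=age_blood, ref=armss_ref)

    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "age": age_blood,
            "age_at_onset": age_onset,
            "symptom_duration": age_blood - age_onset,
            "arr": arr,
            "first_symptom": sites,
            "batch": batch.to_numpy(),
            "treatment": rng.choice(["yes", "no"], n, p=[0.6, 0.4]),
            "smoking": rng.choice(["never", "ever"], n, p=[0.65, 0.35]),
            "parity": rng.choice(["nulliparous", "parous"], n, p=[0.45, 0.55]),
        }
    )
    for s in symptom_site:
        sheet[f"onset_{s}"] = (sites == s).astype(int)

    truth = {
        "dmp_effects": dmp_effects,
        "dmr_regions": dmr_truth,
        "cs_dmps": cs_ids,
        "cs_cell_type": config.cs_cell_type if config.cell_specific_effects else None,
        "mqtl_pairs": pairs,
        "clock_cpgs": clock_ids,
        "clock_model": clock_model,
        "bio_age": pd.Series(bio_age, index=samples),
        "proportions": pd.DataFrame(weights, index=samples, columns=types),
        "group": pd.Series(groups, index=samples),
        "marker_probes": {ct: [probes[i] for i in ids] for ct, ids in marker_ids.items()},
    }
    return SyntheticCohort(
        beta=matrix,
        annotation=annotation,
        sample_sheet=sheet,
        histories=histories,
        genotypes=genotypes,
        snv_metadata=snv_metadata,
        cell_reference=reference_df,
        armss_reference=armss_ref,
        truth=truth,
    )
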