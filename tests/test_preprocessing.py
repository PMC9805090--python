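import numpy as np
import pandas as pd
import pytest

from conftest import toy_annotation
from msewas.containers import MethylationMatrix
from msewas.preprocessing import (
    bmiq_normalize,
    combat_correct,
    filter_probes,
    filter_samples,
    svd_batch_detect,
)
from msewas.synthetic import SimulationConfig, simulate_cohort


def make_matrix(n_probes=10, n_samples=100, seed=0, det_p=None, beads=None):
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:03d}" for i in range(n_probes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    beta = pd.DataFrame(
        rng.uniform(0.1, 0.9, (n_probes, n_samples)), index=probes, columns=samples
    )
    if det_p is None:
        det_p = pd.DataFrame(0.001, index=probes, columns=samples)
    if beads is None:
        beads = pd.DataFrame(10, index=probes, columns=samples)
    return MethylationMatrix(beta=beta, detection_p=det_p, bead_count=beads)


class TestFilterProbes:
    def test_clean_matrix_untouched(self):
        m = make_matrix()
        out, report = filter_probes(m, toy_annotation(m.probes))
        assert report.total_removed == 0
        assert out.n_probes == m.n_probes

    def test_detection_failure_in_exactly_five_percent_removed(self):
        m = make_matrix(n_probes=3, n_samples=100)
        # probe cg000 fails detection in exactly 5 of 100 samples (>= rule)
        m.detection_p.iloc[0, :5] = 0.5
        # probe cg001 fails in 4 of 100 -> kept
        m.detection_p.iloc[1, :4] = 0.5
        out, report = filter_probes(m, toy_annotation(m.probes))
        assert "cg000" not in out.probes
        assert "cg001" in out.probes
        assert report.detection_p == 1

    def test_low_bead_count_rule(self):
        m = make_matrix(n_probes=2, n_samples=40)
        m.bead_count.iloc[0, :2] = 1  # 2/40 = 5% -> removed
        out, report = filter_probes(m, toy_annotation(m.probes))
        assert report.bead_count == 1
        assert out.n_probes == 1

    def test_non_autosomal_probe_removed(self):
        m = make_matrix(n_probes=3)
        ann = toy_annotation(m.probes)
        ann.loc[1, "chromosome"] = "X"
        ann.loc[1, "autosomal"] = False
        out, report = filter_probes(m, ann)
        assert report.non_autosomal == 1
        assert "cg001" not in out.probes

    def test_flagged_probes_removed_and_counts_sum(self):
        m = make_matrix(n_probes=5)
        ann = toy_annotation(m.probes)
        ann.loc[0, "non_cpg"] = True
        ann.loc[1, "snp_related"] = True
        ann.loc[2, "multi_hit"] = True
        out, report = filter_probes(m, ann)
        assert report.total_removed == 3
        assert report.non_cpg + report.snp_related + report.multi_hit == 3
        assert out.n_probes == 2

    def test_missing_annotation_raises(self):
        m = make_matrix(n_probes=3)
        with pytest.raises(ValueError, match="annotation missing"):
            filter_probes(m, toy_annotation(m.probes[:2]))

    def test_rule_order_independence(self):
        # a probe violating several rules is removed exactly once
        m = make_matrix(n_probes=4, n_samples=20)
        m.detection_p.iloc[0] = 0.5
        ann = toy_annotation(m.probes)
        ann.loc[0, "non_cpg"] = True
        out, report = filter_probes(m, ann)
        assert report.total_removed == 1
        assert out.n_probes == 3


class TestFilterSamples:
    def test_failed_ratio_boundaries(self):
        m = make_matrix(n_probes=100, n_samples=3)
        # sample 0: 11 failed -> 11/89 > 0.1 removed
        m.detection_p.iloc[:11, 0] = 0.5
        # sample 1: 9 failed -> 9/91 <= 0.1 kept
        m.detection_p.iloc[:9, 1] = 0.5
        out, removed = filter_samples(m)
        assert removed == ["s000"]
        assert "s001" in out.samples and "s002" in out.samples

    def test_all_samples_failing_is_hard_error(self):
        m = make_matrix(n_probes=10, n_samples=2)
        m.detection_p.iloc[:, :] = 0.5
        with pytest.raises(RuntimeError):
            filter_samples(m)


class TestBmiq:
    @staticmethod
    def _mixture_matrix(shift=0.0, n=600, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        modes = rng.choice([0, 1, 2], size=n, p=[0.4, 0.2, 0.4])
        vals = np.where(
            modes == 0, rng.beta(2, 20, n), np.where(modes == 1, rng.beta(8, 8, n), rng.beta(20, 2, n))
        )
        beta = np.clip(vals, 0.01, 0.99)
        beta[half:] = np.clip(beta[half:] + shift * (beta[half:] < 0.4), 0.01, 0.99)
        probes = [f"cg{i:04d}" for i in range(n)]
        design = pd.Series(["I"] * half + ["II"] * (n - half), index=probes)
        frame = pd.DataFrame({"s1": beta, "s2": np.clip(beta + 0.005, 0.01, 0.99)}, index=probes)
        return MethylationMatrix(beta=frame, design_type=design)

    def test_matched_mixtures_map_near_identity(self):
        m = self._mixture_matrix(shift=0.0)
        out = bmiq_normalize(m)
        type2 = m.probes[m.design_type == "II"]
        delta = (out.beta.loc[type2] - m.beta.loc[type2]).abs()
        assert float(delta.median().median()) < 0.02

    def test_type1_probes_unchanged_and_shape_preserved(self):
        m = self._mixture_matrix(shift=0.1)
        out = bmiq_normalize(m)
        type1 = m.probes[m.design_type == "I"]
        assert np.allclose(out.beta.loc[type1], m.beta.loc[type1])
        assert out.beta.shape == m.beta.shape
        assert list(out.samples) == list(m.samples)

    def test_shifted_unmethylated_mode_realigned(self):
        m = self._mixture_matrix(shift=0.1, seed=3)
        out = bmiq_normalize(m)
        type1 = m.probes[m.design_type == "I"]
        type2 = m.probes[m.design_type == "II"]
        low1 = m.beta.loc[type1, "s1"][m.beta.loc[type1, "s1"] < 0.4]
        raw2 = m.beta.loc[type2, "s1"]
        low2_norm = out.beta.loc[type2, "s1"][raw2 < 0.55]
        # post-normalisation unmethylated mode sits near the type-I mode
        assert abs(low1.median() - low2_norm.median()) < abs(
            low1.median() - raw2[raw2 < 0.55].median()
        )

    def test_output_in_unit_interval(self):
        out = bmiq_normalize(self._mixture_matrix(shift=0.05, seed=5))
        assert (out.beta.to_numpy() > 0).all() and (out.beta.to_numpy() < 1).all()


class TestSvdBatchDetect:
    def test_planted_batch_is_detected_strongly(self):
        cfg = SimulationConfig(
            n_samples=40, n_probes=600, n_truth_dmps=0, n_clock_cpgs=5,
            n_mqtl_pairs=0, n_null_snvs=0, batch_shift=1.0, batch_scale=1.2, seed=5,
        )
        cohort = simulate_cohort(cfg)
        factors = cohort.sample_sheet.set_index("sample_id")[["batch"]]
        table = svd_batch_detect(cohort.beta, factors)
        assert table["p_value"].min() < 1e-6
        assert table["significant"].any()

    def test_null_factor_flags_near_nominal(self, rng):
        probes = [f"cg{i}" for i in range(300)]
        samples = [f"s{i}" for i in range(60)]
        beta = pd.DataFrame(
            1 / (1 + np.exp(-rng.normal(0, 1, (300, 60)))), index=probes, columns=samples
        )
        m = MethylationMatrix(beta=beta)
        fake = pd.DataFrame(
            {f"f{j}": rng.choice(["a", "b", "c"], 60) for j in range(20)}, index=samples
        )
        table = svd_batch_detect(m, fake)
        rate = table["significant"].mean()
        assert rate < 0.05  # ~1% expected at the p<0.01 flag

    def test_constant_factor_skipped(self, rng):
        samples = [f"s{i}" for i in range(10)]
        beta = pd.DataFrame(
            rng.uniform(0.2, 0.8, (50, 10)),
            index=[f"cg{i}" for i in range(50)],
            columns=samples,
        )
        m = MethylationMatrix(beta=beta)
        table = svd_batch_detect(m, pd.DataFrame({"plate": ["P1"] * 10}, index=samples))
        assert (table["note"] == "constant factor skipped").any()


class TestCombat:
    @staticmethod
    def _batched_matrix(shift=0.0, scale=1.0, seed=0, n_probes=400, n_samples=40):
        rng = np.random.default_rng(seed)
        probes = [f"cg{i}" for i in range(n_probes)]
        samples = [f"s{i}" for i in range(n_samples)]
        m = rng.normal(0, 1, (n_probes, n_samples)) + rng.normal(0, 2, (n_probes, 1))
        batch = pd.Series(["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2), index=samples)
        m[:, batch.to_numpy() == "B"] = m[:, batch.to_numpy() == "B"] * scale + shift
        beta = 2.0**m / (2.0**m + 1)
        return MethylationMatrix(beta=pd.DataFrame(beta, index=probes, columns=samples)), batch

    def test_identical_batches_near_identity(self):
        # with no true batch effect, empirical-Bayes shrinkage keeps the
        # adjustment small (it cannot be exactly zero on finite data)
        m, batch = self._batched_matrix(shift=0.0, scale=1.0)
        out = combat_correct(m, batch)
        rel_change = float((out.m - m.m).abs().mean().mean()) / float(
            m.m.abs().mean().mean()
        )
        assert rel_change < 0.05

    def test_planted_shift_removed(self):
        m, batch = self._batched_matrix(shift=1.0, scale=1.0, seed=1)
        out = combat_correct(m, batch)
        mv = out.m
        per_probe_diff = (
            mv.loc[:, batch == "A"].mean(axis=1) - mv.loc[:, batch == "B"].mean(axis=1)
        )
        raw_diff = (
            m.m.loc[:, batch == "A"].mean(axis=1) - m.m.loc[:, batch == "B"].mean(axis=1)
        )
        # the shared +1 shift is removed at cohort level ...
        assert abs(float(per_probe_diff.mean())) < 0.05
        # ... and the bulk of each probe's batch difference is gone
        assert float(per_probe_diff.abs().mean()) < 0.3 * float(raw_diff.abs().mean())

    def test_detection_negligible_after_correction(self):
        cfg = SimulationConfig(
            n_samples=40, n_probes=600, n_truth_dmps=0, n_clock_cpgs=5,
            n_mqtl_pairs=0, n_null_snvs=0, batch_shift=1.0, batch_scale=1.2, seed=5,
        )
        cohort = simulate_cohort(cfg)
        batch = cohort.sample_sheet.set_index("sample_id")["batch"]
        corrected = combat_correct(cohort.beta, batch)
        table = svd_batch_detect(corrected, batch.to_frame())
        assert not table["significant"].any()

    def test_second_application_changes_little(self):
        # shrunk estimates on already-corrected data are near-null, so a
        # second pass moves the matrix far less than the first
        m, batch = self._batched_matrix(shift=0.8, scale=1.3, seed=2)
        once = combat_correct(m, batch)
        twice = combat_correct(once, batch)
        first_change = float((once.m - m.m).abs().mean().mean())
        second_change = float((twice.m - once.m).abs().mean().mean())
        assert second_change < 0.05
        assert second_change < 0.25 * first_change

    def test_shape_and_ids_preserved(self):
        m, batch = self._batched_matrix(shift=0.5)
        out = combat_correct(m, batch)
        assert list(out.probes) == list(m.probes)
        assert list(out.samples) == list(m.samples)

    def test_single_sample_batch_rejected(self):
        m, batch = self._batched_matrix()
        batch.iloc[0] = "C"
        with pytest.raises(ValueError, match="single sample"):
            combat_correct(m, batch)
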