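import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msewas.mqtl import (
    adjusted_association,
    find_cis_snvs,
    genotype_qc,
    hwe_test,
    ld_prune,
    mqtl_test,
)
from msewas.synthetic import inject_mqtl


def hand_rank_kruskal(groups):
    """Textbook tie-corrected Kruskal-Wallis from first principles."""
    all_vals = np.concatenate(groups)
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        offset += len(g)
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(all_vals, return_counts=True)
    tie_correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    h /= tie_correction
    return stats.chi2.sf(h, df=len(groups) - 1)


class TestHwe:
    def test_perfect_equilibrium_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit_closed_form(self):
        # (50, 0, 50): expected (25, 50, 25), chi2 = 100
        p = hwe_test(50, 0, 50)
        assert p == pytest.approx(stats.chi2.sf(100, 1), rel=1e-10)

    def test_chi_square_matches_textbook_formula_on_random_counts(self, rng):
        for _ in range(100):
            counts = rng.integers(10, 200, size=3)
            n = counts.sum()
            freq = (2 * counts[0] + counts[1]) / (2 * n)
            expected = n * np.array(
                [freq**2, 2 * freq * (1 - freq), (1 - freq) ** 2]
            )
            if expected.min() < 5:
                continue
            chi2 = (((counts - expected) ** 2) / expected).sum()
            assert hwe_test(*counts) == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_small_counts_take_exact_branch(self):
        # (1,1,1) expected het count < 5 -> exact test; p must be in (0, 1]
        p = hwe_test(1, 1, 1)
        assert 0 < p <= 1

    def test_exact_probabilities_sum_to_one_implicitly(self):
        # with all mass on the observed configuration the exact p is 1
        assert hwe_test(0, 2, 0) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestGenotypeQc:
    @staticmethod
    def _frame(columns: dict, chromosomes=None):
        g = pd.DataFrame(columns, index=[f"s{i}" for i in range(len(next(iter(columns.values()))))])
        meta = pd.DataFrame(
            {
                "snv_id": list(columns),
                "chromosome": chromosomes or ["1"] * len(columns),
                "position": range(100, 100 + len(columns)),
            }
        )
        return g, meta

    def test_monomorphic_snv_dropped(self, rng):
        good = rng.binomial(2, 0.3, 100)
        g, meta = self._frame({"mono": np.zeros(100), "ok": good})
        out, _, report = genotype_qc(g, meta)
        assert "mono" not in out.columns and "ok" in out.columns
        assert report.total_snvs_removed == 1

    def test_maf_boundary_exactly_005_kept(self):
        # 100 samples, 10 alt alleles -> MAF exactly 0.05 (strict < rule)
        col = np.zeros(100)
        col[:10] = 1
        g, meta = self._frame({"edge": col})
        out, _, report = genotype_qc(g, meta)
        assert "edge" in out.columns
        assert report.maf == 0

    def test_hwe_violation_dropped(self):
        col = np.array([0] * 50 + [2] * 50)  # no heterozygotes at all
        g, meta = self._frame({"bad": col})
        out, _, report = genotype_qc(g, meta)
        assert report.hwe == 1 and len(out.columns) == 0

    def test_low_call_rate_snv_and_sample_dropped(self, rng):
        good = rng.binomial(2, 0.4, 100).astype(float)
        sparse = good.copy()
        sparse[:10] = np.nan  # 90% call rate < 95%
        g, meta = self._frame({"sparse": sparse, "ok1": good,
                               "ok2": rng.binomial(2, 0.3, 100).astype(float)})
        g.iloc[0, 1:] = np.nan  # sample s0 misses every retained SNV
        out, _, report = genotype_qc(g, meta)
        assert report.call_rate == 1
        assert "s0" in report.samples_removed

    def test_non_autosomal_dropped(self, rng):
        col = rng.binomial(2, 0.4, 60)
        g, meta = self._frame({"x_snv": col, "auto": col.copy()},
                              chromosomes=["X", "7"])
        out, _, report = genotype_qc(g, meta)
        assert report.non_autosomal == 1
        assert list(out.columns) == ["auto"]


class TestCis:
    def test_window_boundaries_inclusive(self):
        meta = pd.DataFrame(
            {
                "snv_id": ["at5000", "at5001", "otherchrom"],
                "chromosome": ["3", "3", "4"],
                "position": [105000, 105001, 100000],
            }
        )
        hits = find_cis_snvs("3", 100000, meta, window=5000)
        assert hits == ["at5000"]


class TestLdPrune:
    def test_duplicate_column_pruned_to_one(self, rng):
        col = rng.binomial(2, 0.4, 80).astype(float)
        g = pd.DataFrame({"a": col, "b": col.copy()})
        assert len(ld_prune(g)) == 1

    def test_single_snv_kept(self, rng):
        g = pd.DataFrame({"only": rng.binomial(2, 0.3, 50).astype(float)})
        assert ld_prune(g) == ["only"]

    def test_independent_snvs_usually_both_kept(self):
        kept_both = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            g = pd.DataFrame(
                {
                    "a": r.binomial(2, 0.4, 200).astype(float),
                    "b": r.binomial(2, 0.4, 200).astype(float),
                }
            )
            kept_both += len(ld_prune(g)) == 2
        assert kept_both >= 33  # ~95% expected at the p<0.05 prune rule


class TestMqtlTest:
    def test_identical_values_p_one(self):
        beta = pd.Series([0.5] * 9)
        g = pd.Series([0, 1, 2] * 3)
        assert mqtl_test(beta, g) == pytest.approx(1.0)

    def test_matches_hand_rank_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(6, 30))
            g = pd.Series(rng.integers(0, 3, n))
            if g.nunique() < 2:
                continue
            beta = pd.Series(np.round(rng.uniform(0, 1, n), 2))
            if beta.nunique() == 1:
                continue
            groups = [beta[g == k].to_numpy() for k in sorted(g.unique())]
            assert mqtl_test(beta, g) == pytest.approx(
                hand_rank_kruskal(groups), rel=1e-9
            )

    def test_single_genotype_class_undefined(self):
        assert np.isnan(mqtl_test(pd.Series([0.1, 0.2]), pd.Series([1, 1])))

    def test_planted_mqtl_detected(self, small_cohort):
        for cpg, snv in small_cohort.truth["mqtl_pairs"]:
            p = mqtl_test(small_cohort.beta.beta.loc[cpg], small_cohort.genotypes[snv])
            assert p < 1e-4


class TestInjectMqtl:
    @staticmethod
    def _toy(n=30, seed=0):
        rng = np.random.default_rng(seed)
        beta = pd.DataFrame(
            {f"s{i}": rng.uniform(0.3, 0.7, 3) for i in range(n)},
            index=["cgA", "cgB", "cgC"],
        )
        genotypes = pd.DataFrame(
            {"rs1": np.tile([0, 1, 2], n // 3)}, index=beta.columns
        )
        return beta, genotypes

    def test_zero_effect_is_identity(self):
        beta, genotypes = self._toy()
        out = inject_mqtl(beta, genotypes, [("cgA", "rs1")], effect=0.0)
        assert np.allclose(out, beta, atol=1e-9)

    def test_effect_orders_beta_by_allele_count_other_probes_untouched(self):
        beta, genotypes = self._toy()
        beta.loc["cgA"] = 0.5  # noise off at the target CpG
        out = inject_mqtl(beta, genotypes, [("cgA", "rs1")], effect=0.5)
        means = out.loc["cgA"].groupby(genotypes["rs1"]).mean()
        assert means[0] < means[1] < means[2]
        # three distinct levels, each the inverse logit of 0, 0.5, 1 M-shift
        for g_val in (0, 1, 2):
            expected = 2.0 ** (0.5 * g_val) / (2.0 ** (0.5 * g_val) + 1)
            assert means[g_val] == pytest.approx(expected, abs=1e-9)
        assert np.allclose(out.loc[["cgB", "cgC"]], beta.loc[["cgB", "cgC"]])

    def test_unknown_ids_raise(self):
        beta, genotypes = self._toy()
        with pytest.raises(KeyError):
            inject_mqtl(beta, genotypes, [("nope", "rs1")], effect=0.1)
        with pytest.raises(KeyError):
            inject_mqtl(beta, genotypes, [("cgA", "rsX")], effect=0.1)


class TestAdjustedAssociation:
    def test_constant_genotype_reduces_to_unadjusted(self, rng):
        n = 100
        labels = pd.Series(["mild"] * 50 + ["severe"] * 50)
        beta = pd.Series(
            np.concatenate([rng.normal(0.4, 0.05, 50), rng.normal(0.5, 0.05, 50)])
        )
        g = pd.Series([1] * n)
        out = adjusted_association(labels, beta, g)
        assert not out["genotype_adjusted"]
        assert np.isnan(out["genotype_p"])
        assert out["methylation_p"] < 0.01

    def test_noise_genotype_leaves_methylation_association(self, rng):
        n = 200
        labels = pd.Series(["mild"] * 100 + ["severe"] * 100)
        beta = pd.Series(
            np.concatenate([rng.normal(0.4, 0.05, 100), rng.normal(0.48, 0.05, 100)])
        )
        g = pd.Series(rng.integers(0, 3, n))
        out = adjusted_association(labels, beta, g)
        unadj = adjusted_association(labels, beta, pd.Series([1] * n))
        assert out["methylation_survives_adjustment"]
        assert np.log10(out["methylation_p"]) == pytest.approx(
            np.log10(unadj["methylation_p"]), abs=1.0
        )

    def test_genotype_mediated_methylation_attenuated(self, rng):
        # group depends on genotype; methylation is a pure readout of
        # genotype, so adjusting for genotype removes its signal
        n = 300
        g = pd.Series(rng.integers(0, 3, n))
        prob = 1 / (1 + np.exp(-(g - 1.0)))
        labels = pd.Series(np.where(rng.uniform(size=n) < prob, "severe", "mild"))
        beta = pd.Series(0.3 + 0.1 * g + rng.normal(0, 0.01, n))
        adj = adjusted_association(labels, beta, g)
        unadj = adjusted_association(labels, beta, pd.Series([1] * n))
        assert adj["methylation_p"] > unadj["methylation_p"]
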