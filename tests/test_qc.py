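"""SNP editing rules, frequency summaries, distances, phenotype correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiline_gp.datatypes import MISSING, make_phenotype_table
from multiline_gp.qc import (
    FilterThresholds,
    allele_freq_correlation,
    euclidean_distance_matrix,
    filter_snps,
    fixed_allele_summary,
    precorrect_phenotypes,
    segregating_subset,
    snp_stats,
)
from conftest import make_genotypes


def column(n_hom_ref, n_het, n_hom_alt, n_missing=0):
    return [2] * n_hom_ref + [1] * n_het + [0] * n_hom_alt + [MISSING] * n_missing


class TestSnpStats:
    def test_exact_hwe_proportions_give_zero_chi_square(self):
        geno = make_genotypes(np.array([column(25, 50, 25)]).T)
        stats = snp_stats(geno)
        assert stats["hwe_chi2"].iloc[0] == pytest.approx(0.0)
        assert stats["freq"].iloc[0] == pytest.approx(0.5)

    def test_all_heterozygous_chi_square_hand_value(self):
        # 100 hets: freq 0.5, expected (25, 50, 25) -> chi2 = 25 + 50 + 25
        geno = make_genotypes(np.array([column(0, 100, 0)]).T)
        stats = snp_stats(geno)
        assert stats["freq"].iloc[0] == pytest.approx(0.5)
        assert stats["hwe_chi2"].iloc[0] == pytest.approx(100.0)

    def test_call_rate_arithmetic(self):
        geno = make_genotypes(np.array([column(40, 30, 25, 5)]).T)
        assert snp_stats(geno)["call_rate"].iloc[0] == pytest.approx(0.95)

    def test_frequencies_sum_to_one(self, rng):
        codes = rng.integers(0, 3, size=(50, 30)).astype(np.int8)
        stats = snp_stats(make_genotypes(codes))
        assert np.allclose(stats["freq"] + (1 - stats["freq"]), 1.0)


class TestFilterSnps:
    def test_one_violation_per_rule(self):
        n = 700
        clean = column(210, 308, 182)
        low_call = column(140, 280, 140, 140)            # call rate 0.8
        low_maf = column(0, 26, 674)                     # freq 26/1400 = 0.0186
        all_het = column(0, 700, 0)                      # no homozygote
        hwe_fail = column(350, 0, 350)                   # chi2 = 700
        codes = np.array([clean, clean, low_call, low_maf,
                          clean, all_het, hwe_fail, clean, clean, clean]).T
        geno = make_genotypes(codes)
        report, kept = filter_snps(geno)
        assert report.n_retained == 6
        assert kept.n_snps == 6
        assert report.tags_for("s2") == ["call_rate"]
        assert report.tags_for("s3") == ["maf"]
        assert "no_homozygote" in report.tags_for("s5")
        assert report.tags_for("s6") == ["hwe"]

    def test_maf_threshold_is_exclusive(self):
        # freq exactly 0.02 retained, just below removed
        at = column(0, 20, 480)     # 20/1000 = 0.02
        below = column(0, 19, 481)  # 0.019
        geno = make_genotypes(np.array([at, below]).T)
        report, _ = filter_snps(geno)
        assert bool(report.table["retained"].iloc[0])
        assert not bool(report.table["retained"].iloc[1])

    def test_hwe_cutoff_is_strict_at_600(self):
        geno = make_genotypes(np.array([column(100, 300, 100)]).T)
        stats = snp_stats(geno)
        for chi2, keep in ((600.0, True), (600.01, False)):
            doctored = stats.assign(hwe_chi2=[chi2])
            report, _ = filter_snps(geno, stats=doctored)
            assert bool(report.table["retained"].iloc[0]) is keep

    def test_partition_every_snp_retained_or_tagged(self, rng):
        codes = rng.integers(0, 3, size=(120, 40)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.1] = MISSING
        report, _ = filter_snps(make_genotypes(codes))
        tagged = report.table[list(
            ("call_rate", "maf", "no_homozygote", "hwe"))].any(axis=1)
        assert (report.table["retained"] ^ tagged).all()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_call_rate=1.2)


class TestSegregatingSubset:
    def test_fixed_snp_excluded(self):
        # SNP 1 (index) fixed in both training lines
        codes = np.array([
            [0, 2, 1], [1, 2, 0],   # line A
            [2, 2, 1], [1, 2, 2],   # line B
            [0, 1, 1], [2, 0, 1],   # line C (not training)
        ])
        geno = make_genotypes(codes, lines=["A", "A", "B", "B", "C", "C"])
        assert list(segregating_subset(geno, ["A", "B"])) == [0, 2]

    def test_all_segregating_gives_identity(self, rng):
        codes = np.vstack([np.zeros(10), np.ones(10), 2 * np.ones(10)]).astype(int)
        geno = make_genotypes(codes)
        assert list(segregating_subset(geno, ["L"])) == list(range(10))

    def test_superset_monotonicity(self, small_dataset):
        geno = small_dataset.genotypes
        one = set(segregating_subset(geno, ["B1"]))
        two = set(segregating_subset(geno, ["B1", "W1"]))
        assert one <= two

    def test_unknown_line_rejected(self, small_dataset):
        with pytest.raises(KeyError):
            segregating_subset(small_dataset.genotypes, ["nope"])


class TestFixedAlleles:
    def test_identical_lines_have_no_opposite_fixed(self):
        block = np.array([[2, 0, 1], [2, 0, 1]])
        geno = make_genotypes(np.vstack([block, block]),
                              lines=["A", "A", "B", "B"])
        summary = fixed_allele_summary(geno)
        assert summary["pairwise"][("A", "B")]["opposite_allele"] == 0

    def test_hand_enumerated_pair(self):
        # s0: both fixed ref; s1: A fixed alt, B fixed ref; s2: segregating in A
        a = np.array([[2, 0, 1], [2, 0, 0]])
        b = np.array([[2, 2, 1], [2, 2, 1]])
        geno = make_genotypes(np.vstack([a, b]), lines=["A", "A", "B", "B"])
        summary = fixed_allele_summary(geno)
        pair = summary["pairwise"][("A", "B")]
        assert pair == {"both_fixed": 2, "same_allele": 1, "opposite_allele": 1}
        assert summary["per_line"]["A"] == 2
        assert summary["per_line"]["B"] == 2

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            fixed_allele_summary(make_genotypes(np.array([[0, 1]])))


class TestAlleleFreqCorrelation:
    def test_line_with_itself_is_one(self, small_dataset):
        assert allele_freq_correlation(
            small_dataset.genotypes, "B1", "B1") == pytest.approx(1.0)

    def test_shuffled_frequencies_near_zero(self, rng):
        p = 4000
        fa = rng.uniform(0.05, 0.5, p)
        codes_a = rng.binomial(2, fa, size=(200, p))
        codes_b = rng.binomial(2, rng.permutation(fa), size=(200, p))
        geno = make_genotypes(np.vstack([codes_a, codes_b]).astype(np.int8),
                              lines=["A"] * 200 + ["B"] * 200)
        assert abs(allele_freq_correlation(geno, "A", "B")) < 4 / np.sqrt(p)

    def test_invariant_to_snp_order(self, small_dataset, rng):
        geno = small_dataset.genotypes
        r1 = allele_freq_correlation(geno, "B1", "B2")
        perm = rng.permutation(geno.n_snps)
        r2 = allele_freq_correlation(geno.subset(snp_indices=perm), "B1", "B2")
        assert r1 == pytest.approx(r2)


class TestEuclideanDistance:
    def test_hand_example(self):
        geno = make_genotypes(np.array([[0, 1, 2], [2, 1, 0]]))
        d = euclidean_distance_matrix(geno)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(8.0))
        assert d.iloc[0, 0] == 0.0

    def test_matches_brute_force_double_loop(self, rng):
        codes = rng.integers(0, 3, size=(15, 40)).astype(np.int8)
        geno = make_genotypes(codes)
        d = euclidean_distance_matrix(geno).to_numpy()
        x = codes.astype(float)
        for j in range(15):
            for k in range(15):
                expect = np.sqrt(np.sum((x[j] - x[k]) ** 2))
                assert d[j, k] == pytest.approx(expect, abs=1e-10)

    def test_triangle_inequality(self, rng):
        codes = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        d = euclidean_distance_matrix(make_genotypes(codes)).to_numpy()
        for a in range(12):
            for b in range(12):
                for c in range(12):
                    assert d[a, c] <= d[a, b] + d[b, c] + 1e-9

    def test_missing_values_rejected(self):
        geno = make_genotypes(np.array([[0, MISSING], [1, 2]]))
        with pytest.raises(ValueError):
            euclidean_distance_matrix(geno)


class TestPrecorrectPhenotypes:
    def make_pheno(self, weeks, y):
        n = len(y)
        return make_phenotype_table(
            [f"i{k}" for k in range(n)], ["L"] * n, weeks, y)

    def test_single_hatch_week_centres_only(self, rng):
        y = rng.normal(5.0, 1.0, 40)
        out = precorrect_phenotypes(self.make_pheno([0] * 40, y))
        assert np.allclose(out["y_corrected"], y - y.mean())

    def test_constant_offset_between_hatches_removed(self, rng):
        base = rng.normal(0.0, 1.0, 30)
        y = np.concatenate([base, base + 7.5])
        weeks = [0] * 30 + [1] * 30
        out = precorrect_phenotypes(self.make_pheno(weeks, y))
        g0 = out.loc[out["hatch_week"] == 0, "y_corrected"].mean()
        g1 = out.loc[out["hatch_week"] == 1, "y_corrected"].mean()
        assert abs(g0 - g1) < 1e-10

    def test_idempotent(self, rng):
        y = rng.normal(0.0, 2.0, 50)
        weeks = (np.arange(50) % 3).tolist()
        once = precorrect_phenotypes(self.make_pheno(weeks, y))
        twice = precorrect_phenotypes(
            once.assign(y=once["y_corrected"]))
        assert np.allclose(once["y_corrected"], twice["y_corrected"])

    def test_residuals_orthogonal_to_hatch_indicators(self, rng):
        y = rng.normal(0.0, 1.0, 60) + np.repeat([0.0, 2.0, -1.0], 20)
        weeks = np.repeat([0, 1, 2], 20).tolist()
        out = precorrect_phenotypes(self.make_pheno(weeks, y))
        for w in (0, 1, 2):
            ind = (out["hatch_week"] == w).to_numpy(dtype=float)
            contrast = ind - ind.mean()
            assert abs(out["y_corrected"] @ contrast) < 1e-8

    def test_fit_on_training_only_excludes_validation_leakage(self, rng):
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 10)])
        pheno = self.make_pheno([0] * 40, y)
        fit_ids = [f"i{k}" for k in range(30)]
        out = precorrect_phenotypes(pheno, fit_ids=fit_ids)
        # correction uses the training mean, not the overall mean
        assert np.allclose(out["y_corrected"], y - y[:30].mean())

    def test_unseen_hatch_week_rejected(self):
        pheno = self.make_pheno([0] * 5 + [1] * 5, np.arange(10.0))
        with pytest.raises(ValueError):
            precorrect_phenotypes(pheno, fit_ids=[f"i{k}" for k in range(5)])


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_snp_stats_hwe_nonnegative_property(seed):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
    stats = snp_stats(make_genotypes(codes))
    assert (stats["hwe_chi2"].dropna() >= 0).all()
    assert stats["call_rate"].between(0, 1).all()
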