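"""Inference layer: classification, region tests, exact tests, diagnostics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolfst import (
    ContractError,
    RegionSpec,
    between_population_fst,
    category_overrepresentation,
    central_third,
    chromosome_enrichment,
    classify_high_fst,
    fit_beta,
    intersect_populations,
    male_hexp_test,
    region_summary,
    variant_alignment_ratio,
)


def hypergeom_upper_tail(k, N, K, n) -> Fraction:
    """Exact P(X >= k), X ~ Hypergeom(N, K, n), by direct pmf summation."""
    total = Fraction(0)
    for x in range(max(k, 0, K + n - N), min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return total


def gene_frame(fsts, chroms=None, hexp_m=None, hexp_f=None, mids=None):
    n = len(fsts)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "chrom": chroms or ["chr1"] * n,
        "midpoint": mids if mids is not None else np.arange(10, 10 * n + 1, 10),
        "fst": fsts,
        "mean_hexp_male": hexp_m if hexp_m is not None else [0.1] * n,
        "mean_hexp_female": hexp_f if hexp_f is not None else [0.1] * n,
    })


class TestClassifyHighFst:
    def test_boundary_inclusive_and_undefined_excluded(self):
        df = gene_frame([0.100, 0.0999, np.nan, 0.5])
        out = classify_high_fst(df)
        assert list(out["flagged"]) == [True, False, False, True]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        df = gene_frame(rng.beta(1, 6, size=200))
        counts = [classify_high_fst(df, t)["flagged"].sum() for t in (0.05, 0.1, 0.2, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_domain(self):
        with pytest.raises(ContractError):
            classify_high_fst(gene_frame([0.1]), threshold=0.0)


class TestMaleHexpTest:
    def test_identical_vectors_no_evidence(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(0.05, 0.3, 100)
        res = male_hexp_test(gene_frame([0.1] * 100, hexp_m=h, hexp_f=h.copy()))
        assert res.p_value == pytest.approx(0.5)
        assert res.statistic == pytest.approx(0.0)

    def test_shifted_means_reject_and_match_closed_form(self):
        rng = np.random.default_rng(1)
        f = rng.normal(0.15, 0.04, 200)
        m = f + 0.05
        res = male_hexp_test(gene_frame([0.1] * 200, hexp_m=m, hexp_f=f))
        assert res.p_value < 1e-10
        # Welch t against the reference computation
        t_ref, p_ref = stats.ttest_ind(m, f, equal_var=False, alternative="greater")
        assert res.statistic == pytest.approx(float(t_ref))
        assert res.p_value == pytest.approx(float(p_ref))

    def test_one_sidedness(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0.10, 0.02, 50)
        res = male_hexp_test(gene_frame([0.1] * 50, hexp_m=m, hexp_f=m + 0.05))
        assert res.p_value > 0.5

    def test_direction_swap_complementarity(self):
        rng = np.random.default_rng(4)
        df = gene_frame([0.1] * 60, hexp_m=rng.uniform(0, 0.5, 60),
                        hexp_f=rng.uniform(0, 0.5, 60))
        p_mf = male_hexp_test(df).p_value
        p_fm = male_hexp_test(df, male="female", female="male").p_value
        assert p_mf + p_fm >= 1.0 - 1e-12

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        df = gene_frame([0.1] * 40, hexp_m=rng.uniform(0, 0.5, 40),
                        hexp_f=rng.uniform(0, 0.5, 40))
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        assert male_hexp_test(df).p_value == pytest.approx(male_hexp_test(shuffled).p_value)

    def test_paired_mode_uses_pairing(self):
        rng = np.random.default_rng(6)
        f = rng.uniform(0.05, 0.45, 50)
        m = f + 0.01  # constant within-gene shift: overwhelming when paired
        df = gene_frame([0.1] * 50, hexp_m=m, hexp_f=f)
        assert male_hexp_test(df, mode="paired").p_value < 1e-20
        assert male_hexp_test(df, mode="unpaired").p_value > 1e-3

    def test_too_few_genes_warns_with_undefined_p(self):
        df = gene_frame([0.1], hexp_m=[0.2], hexp_f=[0.1])
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = male_hexp_test(df)
        assert np.isnan(res.p_value)

    def test_region_restriction(self):
        df = gene_frame([0.1] * 6, hexp_m=[0.5, 0.5, 0.5, 0.0, 0.0, 0.0],
                        hexp_f=[0.1] * 6, mids=[10, 20, 30, 110, 120, 130])
        region = RegionSpec("chr1", 1, 100, "left")
        res = male_hexp_test(df, region)
        assert res.n["male"] == 3 and res.region_label == "left"


class TestChromosomeEnrichment:
    def make(self, per_chrom_flagged):
        rows, flagged = [], []
        for c, (n, k) in per_chrom_flagged.items():
            for i in range(n):
                gid = f"{c}_g{i}"
                rows.append({"gene_id": gid, "chrom": c, "midpoint": i,
                             "fst": 0.2 if i < k else 0.01,
                             "mean_hexp_male": 0.1, "mean_hexp_female": 0.1})
                if i < k:
                    flagged.append(gid)
        return pd.DataFrame(rows), flagged

    def test_matches_exact_hypergeometric_tail(self):
        df, flagged = self.make({"chr1": (20, 8), "chr2": (20, 1)})
        res = {r.region_label: r for r in chromosome_enrichment(df, flagged)}
        # chr1: N=40 genes, K=9 flagged, n=20 on chr1, k=8
        expect = hypergeom_upper_tail(8, 40, 9, 20)
        assert res["chr1"].p_value == pytest.approx(float(expect), rel=1e-9)

    def test_identical_proportions_not_enriched(self):
        df, flagged = self.make({"chr1": (30, 3), "chr2": (30, 3), "chr3": (30, 3)})
        for r in chromosome_enrichment(df, flagged):
            assert r.p_value >= 0.5

    def test_all_flagged_on_one_chromosome(self):
        df, flagged = self.make({"chr1": (30, 12), "chr2": (30, 0), "chr3": (30, 0)})
        res = {r.region_label: r for r in chromosome_enrichment(df, flagged)}
        assert res["chr1"].p_value < 1e-6
        assert res["chr2"].p_value > 0.5

    def test_single_chromosome_rejected(self):
        df, flagged = self.make({"chr1": (10, 2)})
        with pytest.raises(ContractError):
            chromosome_enrichment(df, flagged)


class TestCategoryOverrepresentation:
    def test_worked_hypergeometric_case(self):
        universe = {f"g{i}": ("cat" if i < 10 else "rest") for i in range(100)}
        selected = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(50, 55)]
        res = {r.region_label: r for r in category_overrepresentation(universe, selected)}
        expect = hypergeom_upper_tail(5, 100, 10, 10)
        assert res["cat"].p_value == pytest.approx(float(expect), rel=1e-9)

    def test_category_covering_universe_is_uninformative(self):
        universe = {f"g{i}": "all" for i in range(30)}
        res = category_overrepresentation(universe, [f"g{i}" for i in range(5)])
        assert res[0].p_value == pytest.approx(1.0)

    def test_zero_overlap_is_uninformative(self):
        universe = {f"g{i}": ("cat" if i < 5 else "rest") for i in range(50)}
        res = {r.region_label: r
               for r in category_overrepresentation(universe, [f"g{i}" for i in range(10, 20)])}
        assert res["cat"].p_value == pytest.approx(1.0)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ContractError):
            category_overrepresentation({"g1": "c"}, ["gX"])


class TestIntersection:
    def test_basic_intersection(self):
        common, tally = intersect_populations(
            {"g1", "g2", "g3"}, {"g2", "g3", "g4"},
            {"g2": "chr1", "g3": "chr2"},
        )
        assert common == ["g2", "g3"]
        assert tally == {"chr1": 1, "chr2": 1}

    def test_disjoint_and_subset(self):
        assert intersect_populations({"a"}, {"b"})[0] == []
        assert intersect_populations({"a", "b"}, {"a", "b", "c"})[0] == ["a", "b"]


class TestBetweenPopulationFst:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "A", "C", "G", "T"])

    def test_identical_populations_have_no_between_variance(self):
        rows = [("chr1", i * 10, "A", 60, 20, 0, 0) for i in range(1, 6)]
        out = between_population_fst(self.frame(rows), self.frame(rows))
        defined = out["fst"].dropna()
        assert len(defined) == 5 and (defined <= 1e-12).all()

    def test_fixed_difference_gives_fst_one(self):
        x = self.frame([("chr1", 10, "A", 50, 0, 0, 0)])
        y = self.frame([("chr1", 10, "A", 0, 50, 0, 0)])
        out = between_population_fst(x, y)
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_cross_population_monomorphic_dropped(self):
        x = self.frame([("chr1", 10, "A", 0, 50, 0, 0)])
        y = self.frame([("chr1", 10, "A", 0, 45, 0, 0)])
        assert len(between_population_fst(x, y)) == 0

    def test_schema_matches_intersex_site_stats(self):
        x = self.frame([("chr1", 10, "A", 40, 10, 0, 0)])
        y = self.frame([("chr1", 10, "A", 30, 20, 0, 0)])
        out = between_population_fst(x, y, labels=("A_f", "B_f"))
        for col in ("chrom", "pos", "ref", "variant", "p_A_f", "p_B_f",
                    "cov_A_f", "cov_B_f", "hexp_A_f", "hexp_B_f", "a", "b", "fst"):
            assert col in out.columns


class TestBetaFit:
    def test_method_of_moments_identity(self):
        rng = np.random.default_rng(8)
        x = rng.beta(2.0, 5.0, 500)
        fit = fit_beta(x)
        m, v = fit["mean"], fit["var"]
        assert fit["alpha"] == pytest.approx(m * (m * (1 - m) / v - 1), rel=1e-12)

    def test_constant_input_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            fit = fit_beta([0.3] * 20)
        assert np.isnan(fit["alpha"])

    def test_too_few_values_rejected(self):
        with pytest.raises(ContractError):
            fit_beta([0.1, 0.2])

    def test_recovery_at_moderate_n(self):
        rng = np.random.default_rng(9)
        fit = fit_beta(rng.beta(2.0, 5.0, 5000))
        assert fit["alpha"] == pytest.approx(2.0, rel=0.15)
        assert fit["beta"] == pytest.approx(5.0, rel=0.15)


class TestVariantAlignmentRatio:
    def test_arithmetic(self):
        assert variant_alignment_ratio(2000, 1_000_000, 100) == pytest.approx(0.02)

    def test_zero_variants(self):
        assert variant_alignment_ratio(0, 1000) == 0.0

    def test_homogeneity(self):
        assert variant_alignment_ratio(500, 2_000_000) == pytest.approx(
            variant_alignment_ratio(1000, 4_000_000)
        )

    def test_zero_aligned_reads_rejected(self):
        with pytest.raises(ContractError):
            variant_alignment_ratio(10, 0)


def test_central_third_bounds():
    r = central_third("chr1", 300000)
    assert (r.start, r.end) == (100001, 200000)


def test_region_summary_layout():
    rng = np.random.default_rng(10)
    df = gene_frame([0.1] * 50, hexp_m=rng.uniform(0, 0.4, 50),
                    hexp_f=rng.uniform(0, 0.4, 50),
                    mids=np.arange(50) * 100 + 50)
    regions = [RegionSpec("chr1", 1, 5000, "whole"), RegionSpec("chr1", 1000, 2000, "mid")]
    out = region_summary(df, regions, ("female", "male"))
    assert len(out) == 4  # 2 regions x 2 groups
    assert set(out.columns) >= {"region", "group", "n_genes", "mean", "median",
                                "variance", "sd", "ci95_half_width", "male_excess_p"}
    whole_male = out[(out["region"] == "whole") & (out["group"] == "male")].iloc[0]
    assert whole_male["n_genes"] == 50
    assert whole_male["ci95_half_width"] == pytest.approx(1.96 * whole_male["sd"])
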