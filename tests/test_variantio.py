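import numpy as np
import pandas as pd
import pytest

from heatgs.simpop import apply_gbs_missingness
from heatgs.variantio import (FilterConfig, VcfParseError, density_windows,
                              filter_markers, marker_diversity,
                              phenotype_summary, pic_biallelic, read_vcf,
                              tstv, write_vcf)

from conftest import make_matrix


def _write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
]


class TestVcfIO:
    def test_gt_encoding(self, tmp_path):
        """0/0, 0/1, 1/1 and ./. map to -1, 0, +1 and NaN."""
        vcf = tmp_path / "toy.vcf"
        _write_lines(vcf, VCF_HEADER + [
            "Chr01\t100\tm1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
            "Chr01\t200\tm2\tC\tT\t.\t.\t.\tGT\t./.\t1/1\t0/0",
        ])
        gm = read_vcf(vcf)
        np.testing.assert_array_equal(gm.dosage[:, 0], [-1, 0, 1])
        assert np.isnan(gm.dosage[0, 1])
        np.testing.assert_array_equal(gm.dosage[1:, 1], [1, -1])
        assert gm.line_ids == ["s1", "s2", "s3"]

    def test_non_biallelic_records_skipped(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        body = [f"Chr01\t{100 * (i + 1)}\tm{i}\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1"
                for i in range(4)]
        body.insert(2, "Chr01\t250\tmx\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/2")
        _write_lines(vcf, VCF_HEADER + body)
        gm = read_vcf(vcf)
        assert gm.n_markers == 4
        assert gm.n_skipped == 1

    def test_indel_records_skipped(self, tmp_path):
        vcf = tmp_path / "indel.vcf"
        _write_lines(vcf, VCF_HEADER + [
            "Chr01\t100\tm1\tAT\tA\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
            "Chr01\t200\tm2\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
        ])
        assert read_vcf(vcf).n_markers == 1

    def test_empty_vcf_raises(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        _write_lines(vcf, VCF_HEADER)
        with pytest.raises(VcfParseError):
            read_vcf(vcf)

    def test_roundtrip_preserves_matrix(self, tmp_path, small_pop):
        cfg, mats, _ = small_pop
        gm = apply_gbs_missingness(mats["F4"], cfg)
        write_vcf(gm, tmp_path / "rt.vcf")
        back = read_vcf(tmp_path / "rt.vcf")
        assert back.line_ids == gm.line_ids
        pd.testing.assert_frame_equal(back.markers, gm.markers)
        np.testing.assert_array_equal(
            np.nan_to_num(back.dosage, nan=9), np.nan_to_num(gm.dosage, nan=9)
        )

    def test_fractional_dosages_not_writable(self):
        gm = make_matrix([[0.5, -1.0]])
        with pytest.raises(ValueError):
            write_vcf(gm, "/dev/null")


class TestFilters:
    def test_maf_boundary_rule(self):
        """Only markers with MAF strictly below the cutoff are removed."""
        # MAFs 0.0, 0.04, 0.05, 0.10, 0.30, 0.50 built from 50 lines
        n = 50
        cols = []
        for k_alt in (0, 4, 5, 10, 30, 50):  # alt-allele counts out of 2n=100
            col = np.full(n, -1.0)
            col[: k_alt // 2] = 1.0
            if k_alt % 2:
                col[k_alt // 2] = 0.0
            cols.append(col)
        gm = make_matrix(np.column_stack(cols))
        np.testing.assert_allclose(gm.maf(), [0, 0.04, 0.05, 0.10, 0.30, 0.50])
        out = filter_markers(gm, FilterConfig(maf_min=0.05, pemv_level=0))
        assert out.n_markers == 4
        np.testing.assert_allclose(out.maf(), [0.05, 0.10, 0.30, 0.50])

    def test_pemv_call_rate_threshold(self):
        rates = [1.0, 0.92, 0.85, 0.60]
        n = 25
        cols = []
        for cr in rates:
            col = np.zeros(n)
            col[int(round(cr * n)):] = np.nan
            cols.append(col)
        d = np.column_stack(cols)
        d[0, :] = 1.0  # keep markers polymorphic-ish for MAF
        gm = make_matrix(d)
        out = filter_markers(gm, FilterConfig(maf_min=0.0, pemv_level=90))
        assert out.n_markers == 2

    def test_pemv_monotone_and_idempotent(self, small_pop):
        cfg, mats, _ = small_pop
        gm = apply_gbs_missingness(mats["F4"], cfg)
        counts = [
            filter_markers(gm, FilterConfig(maf_min=0.05, pemv_level=p)).n_markers
            for p in (70, 75, 80, 85, 90)
        ]
        assert sorted(counts, reverse=True) == counts
        f = FilterConfig(maf_min=0.05, pemv_level=80)
        once = filter_markers(gm, f)
        twice = filter_markers(once, f)
        assert twice.n_markers == once.n_markers

    def test_filters_commute(self, small_pop):
        cfg, mats, _ = small_pop
        gm = apply_gbs_missingness(mats["F4"], cfg)
        a = filter_markers(
            filter_markers(gm, FilterConfig(maf_min=0.05, pemv_level=0)),
            FilterConfig(maf_min=0.0, pemv_level=85),
        )
        b = filter_markers(
            filter_markers(gm, FilterConfig(maf_min=0.0, pemv_level=85)),
            FilterConfig(maf_min=0.05, pemv_level=0),
        )
        assert list(a.markers["id"]) == list(b.markers["id"])

    def test_all_removed_warns_not_raises(self):
        gm = make_matrix(np.full((10, 3), -1.0))  # all monomorphic
        out = filter_markers(gm, FilterConfig(maf_min=0.05, pemv_level=0))
        assert out.n_markers == 0
        assert out.n_lines == 10


class TestSummaries:
    def test_tstv_definition(self):
        gm = make_matrix(np.zeros((2, 3)), ref=["A", "C", "A"], alt=["G", "T", "C"])
        ts, tv, ratio = tstv(gm)
        assert (ts, tv, ratio) == (2, 1, 2.0)

    def test_tstv_all_transversions_and_inf(self):
        gm = make_matrix(np.zeros((2, 3)), ref=["A"] * 3, alt=["T"] * 3)
        ts, tv, ratio = tstv(gm)
        assert (ts, tv, ratio) == (0, 3, 0.0)
        gm2 = make_matrix(np.zeros((2, 2)), ref=["A", "C"], alt=["G", "T"])
        assert tstv(gm2)[2] == float("inf")

    def test_pic_closed_forms(self):
        assert pic_biallelic(0.5) == pytest.approx(0.375)
        assert pic_biallelic(1.0) == 0.0
        assert pic_biallelic(0.0) == 0.0

    def test_diversity_het_and_monomorphic(self):
        d = np.array([[0.0, -1.0], [0.0, -1.0], [0.0, -1.0]])
        div = marker_diversity(make_matrix(d))
        pm = div["per_marker"]
        assert pm["H"].iloc[0] == 1.0          # all-heterozygous column
        assert pm["H"].iloc[1] == 0.0          # monomorphic column
        assert pm["PIC"].iloc[1] == 0.0
        assert div["tstv"]["ts"] + div["tstv"]["tv"] == 2

    def test_diversity_line_permutation_invariant(self, small_pop):
        _, mats, _ = small_pop
        gm = mats["F4"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(gm.n_lines)
        shuffled = gm.subset_lines(perm)
        a = marker_diversity(gm)["per_marker"]
        b = marker_diversity(shuffled)["per_marker"]
        pd.testing.assert_frame_equal(a, b)

    def test_density_windows(self):
        gm = make_matrix(np.zeros((1, 3)), pos=[10, 20, 1_000_010])
        out = density_windows(gm, 1_000_000)
        assert list(out["n_snps"]) == [2, 1]
        assert out["n_snps"].sum() == 3
        # permutation invariance comes from the sorted-marker invariant
        gm2 = make_matrix(np.zeros((1, 3)), pos=[1_000_010, 20, 10])
        gm2.markers = gm2.markers.sort_values("pos").reset_index(drop=True)
        assert list(density_windows(gm2, 1_000_000)["n_snps"]) == [2, 1]


class TestPhenotypeSummary:
    def test_duplicated_and_anticorrelated_traits(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        df = pd.DataFrame({"A": y, "B": y, "C": -y})
        out = phenotype_summary(df)
        corr = out["correlations"].set_index(["trait_a", "trait_b"])
        assert corr.loc[("A", "B"), "r"] == pytest.approx(1.0)
        assert corr.loc[("A", "C"), "r"] == pytest.approx(-1.0)
        assert out["traits"].loc["A", "mean"] == out["traits"].loc["B", "mean"]

    def test_independent_traits_null_bound(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["A", "B"])
        r = phenotype_summary(df)["correlations"]["r"].iloc[0]
        assert abs(r) < 0.1

    def test_constant_trait_reported_missing(self):
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0], "B": [5.0] * 4})
        corr = phenotype_summary(df)["correlations"]
        assert np.isnan(corr["r"].iloc[0])

    def test_bonferroni_factor_is_pair_count(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("ABCD"))
        df["B"] = df["A"] * 0.5 + rng.normal(size=40) * 0.1
        out = phenotype_summary(df)["correlations"]
        from scipy import stats
        sub = df[["A", "B"]]
        raw_p = stats.pearsonr(sub["A"], sub["B"]).pvalue
        row = out.set_index(["trait_a", "trait_b"]).loc[("A", "B")]
        assert row["p_bonferroni"] == pytest.approx(min(1.0, raw_p * 6))
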