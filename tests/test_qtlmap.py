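import numpy as np
import pandas as pd
import pytest

from heatgs.genmap import kosambi_inverse
from heatgs.qtlmap import (LodCurve, ScanConfig, bayes_interval, cim_scan,
                           estimate_map, genotype_probabilities,
                           permutation_threshold, sim_scan, summarize_qtl,
                           variance_explained)
from heatgs.simpop import SimConfig, simulate_ssd_population

from conftest import make_matrix


@pytest.fixture(scope="module")
def f2_chrom():
    cfg = SimConfig(n_chrom=1, chrom_length_cM=80.0, n_markers=25, n_lines=150,
                    rare_marker_frac=0.0, generations=("F2",), seed=31)
    mats, truth = simulate_ssd_population(cfg)
    return mats["F2"], truth


class TestEstimateMap:
    def test_identical_columns_zero_distance(self):
        col = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0] * 10)
        gm = make_matrix(np.column_stack([col, col]))
        emap = estimate_map(gm)
        assert emap.chromosomes["Chr01"][1] == pytest.approx(0.0, abs=1e-4)

    def test_quarter_recombination_inverse_kosambi(self):
        """A pair with r-hat = 0.25 maps to 0.25 ln 3 Morgans = 27.465 cM."""
        rng = np.random.default_rng(0)
        n = 4000
        # construct two F2-like loci with recombination exactly r = 0.25
        r = 0.25
        gam = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
        p = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
        g1 = gam[rng.choice(4, size=n, p=p)]
        g2 = gam[rng.choice(4, size=n, p=p)]
        d = np.column_stack([g1[:, 0] + g2[:, 0] - 1.0, g1[:, 1] + g2[:, 1] - 1.0])
        emap = estimate_map(make_matrix(d))
        est = emap.chromosomes["Chr01"][1]
        assert est == pytest.approx(kosambi_inverse(0.25), rel=0.08)
        assert kosambi_inverse(0.25) == pytest.approx(27.465, abs=1e-3)

    def test_recovers_simulated_length(self):
        """Estimated chromosome length within +/-20 percent of truth (F2)."""
        rels = []
        for s in range(8):
            cfg = SimConfig(n_chrom=1, chrom_length_cM=50.0, n_markers=15,
                            n_lines=200, rare_marker_frac=0.0,
                            generations=("F2",), seed=800 + s)
            mats, truth = simulate_ssd_population(cfg)
            est = estimate_map(mats["F2"]).total_length
            rels.append(est / truth.map.total_length)
        assert abs(np.mean(rels) - 1.0) < 0.2

    def test_single_marker_chromosome_zero_length(self):
        gm = make_matrix(np.array([[1.0], [-1.0], [0.0]]))
        emap = estimate_map(gm)
        assert emap.total_length == 0.0


class TestGenotypeProbabilities:
    def test_observed_marker_is_certain(self, f2_chrom):
        gm, truth = f2_chrom
        pos = truth.map.chromosomes["Chr01"]
        W = genotype_probabilities(gm.dosage, pos, pos[[3]], error_prob=0.0)
        g = gm.dosage[:, 3]
        obs = ~np.isnan(g)
        picked = W[obs, 0, :].argmax(axis=1) - 1
        np.testing.assert_array_equal(picked, g[obs])
        np.testing.assert_allclose(W[obs, 0].max(axis=1), 1.0)

    def test_probabilities_normalized_everywhere(self, f2_chrom):
        gm, truth = f2_chrom
        pos = truth.map.chromosomes["Chr01"]
        grid = np.linspace(pos[0], pos[-1], 40)
        W = genotype_probabilities(gm.dosage, pos, grid)
        np.testing.assert_allclose(W.sum(axis=2), 1.0, atol=1e-12)


class TestSimScan:
    def test_marker_regression_oracle(self, f2_chrom):
        """At a fully observed marker the EM LOD equals the 3-class
        regression LOD (n/2) log10(RSS0/RSS1)."""
        gm, truth = f2_chrom
        rng = np.random.default_rng(1)
        x = gm.dosage[:, 12]
        y = 0.7 * x + rng.normal(size=gm.n_lines)
        curve = sim_scan(gm, y, truth.map, ScanConfig(step_cM=2.0, error_prob=0.0))
        pos = truth.map.chromosomes["Chr01"][12]
        n = gm.n_lines
        X = np.column_stack([np.ones(n), x, (x == 0).astype(float)])
        rss1 = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        oracle = n / 2 * np.log10(rss0 / rss1)
        got = curve.table.loc[np.isclose(curve.table["cM"], pos), "lod"].iloc[0]
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_lod_nonnegative_and_affine_invariant(self, f2_chrom):
        gm, truth = f2_chrom
        rng = np.random.default_rng(2)
        y = rng.normal(size=gm.n_lines)
        c1 = sim_scan(gm, y, truth.map, ScanConfig(step_cM=4.0))
        c2 = sim_scan(gm, -2.0 * y + 7.0, truth.map, ScanConfig(step_cM=4.0))
        assert (c1.table["lod"] >= 0).all()
        np.testing.assert_allclose(c1.table["lod"], c2.table["lod"], atol=1e-6)

    def test_constant_trait_rejected(self, f2_chrom):
        gm, truth = f2_chrom
        with pytest.raises(ValueError):
            sim_scan(gm, np.ones(gm.n_lines), truth.map)

    def test_planted_qtl_localized(self):
        hits = 0
        n_rep = 10
        for s in range(n_rep):
            cfg = SimConfig(n_chrom=2, chrom_length_cM=80.0, n_markers=40,
                            n_lines=200, rare_marker_frac=0.0,
                            generations=("F2",), seed=850 + s)
            mats, truth = simulate_ssd_population(cfg)
            gm = mats["F2"]
            rng = np.random.default_rng(s)
            j = 10  # marker on Chr01
            x = gm.dosage[:, j]
            g = x / x.std(ddof=1) * np.sqrt(0.30)
            y = g + rng.normal(size=200) * np.sqrt(0.70)
            curve = sim_scan(gm, y, truth.map, ScanConfig(step_cM=1.0))
            chrom, peak_cM, _ = curve.peak()
            true_cM = truth.map.chromosomes["Chr01"][j]
            if chrom == "Chr01" and abs(peak_cM - true_cM) <= 10.0:
                hits += 1
        assert hits >= int(0.8 * n_rep)


class TestCimScan:
    def test_zero_covariates_reduces_to_sim(self, f2_chrom):
        gm, truth = f2_chrom
        rng = np.random.default_rng(3)
        y = gm.dosage[:, 5] + rng.normal(size=gm.n_lines)
        sc = ScanConfig(step_cM=4.0, n_marcovar=0)
        np.testing.assert_allclose(
            cim_scan(gm, y, truth.map, sc).table["lod"],
            sim_scan(gm, y, truth.map, sc).table["lod"],
        )

    def test_saturation_rejected(self, f2_chrom):
        gm, truth = f2_chrom
        y = gm.dosage[:, 5] + 0.1
        y[0] += 1
        with pytest.raises(ValueError, match="saturation"):
            cim_scan(gm, y, truth.map, ScanConfig(n_marcovar=gm.n_lines))

    def test_cim_matches_sim_peak_single_qtl(self):
        agree = 0
        n_rep = 8
        for s in range(n_rep):
            cfg = SimConfig(n_chrom=1, chrom_length_cM=80.0, n_markers=20,
                            n_lines=150, rare_marker_frac=0.0,
                            generations=("F2",), seed=870 + s)
            mats, truth = simulate_ssd_population(cfg)
            gm = mats["F2"]
            rng = np.random.default_rng(s)
            x = gm.dosage[:, 10]
            y = x * 0.8 + rng.normal(size=150)
            sc = ScanConfig(step_cM=2.0, n_marcovar=3, window_cM=15.0)
            p_sim = sim_scan(gm, y, truth.map, sc).peak()[1]
            p_cim = cim_scan(gm, y, truth.map, sc).peak()[1]
            if abs(p_sim - p_cim) <= 2.0:
                agree += 1
        assert agree >= int(0.75 * n_rep)

    def test_cim_separates_linked_qtl_better(self):
        """Two linked QTL in repulsion 40 cM apart: CIM resolves both peaks
        at least as often as SIM."""
        def n_peaks(curve, thr=2.0):
            lod = curve.table["lod"].to_numpy()
            pos = curve.table["cM"].to_numpy()
            above = lod > thr
            # count separated runs above threshold
            runs = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]) == 1)
            return len(runs) if above.any() else 0

        cim_wins = sim_wins = 0
        for s in range(6):
            cfg = SimConfig(n_chrom=1, chrom_length_cM=100.0, n_markers=30,
                            n_lines=250, rare_marker_frac=0.0,
                            generations=("F2",), seed=880 + s)
            mats, truth = simulate_ssd_population(cfg)
            gm = mats["F2"]
            pos = truth.map.chromosomes["Chr01"]
            j1 = int(np.argmin(np.abs(pos - 25)))
            j2 = int(np.argmin(np.abs(pos - 65)))
            rng = np.random.default_rng(s)
            # repulsion: effects of opposite sign
            g = gm.dosage[:, j1] - gm.dosage[:, j2]
            y = g / g.std(ddof=1) * np.sqrt(0.4) + rng.normal(size=250) * np.sqrt(0.6)
            sc = ScanConfig(step_cM=2.0, n_marcovar=4, window_cM=15.0)
            cim_wins += n_peaks(cim_scan(gm, y, truth.map, sc)) >= 2
            sim_wins += n_peaks(sim_scan(gm, y, truth.map, sc)) >= 2
        assert cim_wins >= sim_wins


class TestPermutations:
    def test_determinism_and_alpha_one(self, f2_chrom):
        gm, truth = f2_chrom
        rng = np.random.default_rng(4)
        y = rng.normal(size=gm.n_lines)
        sc = ScanConfig(step_cM=4.0, n_perm=20, seed=9)
        t1 = permutation_threshold(gm, y, truth.map, sc)
        t2 = permutation_threshold(gm, y, truth.map, sc)
        assert t1 == t2 > 0
        sc_min = ScanConfig(step_cM=4.0, n_perm=20, seed=9, alpha=0.999)
        assert permutation_threshold(gm, y, truth.map, sc_min) <= t1


class TestVarianceExplained:
    def test_closed_form_and_roundtrip(self):
        assert variance_explained(0.0, 100) == 0.0
        assert variance_explained(26.14, 100) == pytest.approx(0.70, abs=5e-4)
        for x in (0.0, 0.25, 0.5, 0.86):
            lod = -(50 / 2) * np.log10(1 - x)
            assert variance_explained(lod, 50) == pytest.approx(x, abs=1e-12)

    def test_monotone_and_domain(self):
        lods = np.linspace(0, 30, 50)
        h2 = variance_explained(lods, 80)
        assert np.all(np.diff(h2) > 0)
        assert np.all((h2 >= 0) & (h2 < 1))
        with pytest.raises(ValueError):
            variance_explained(-1.0, 80)


class TestBayesInterval:
    def _curve(self, lod, pos=None, markers=None):
        n = len(lod)
        pos = pos if pos is not None else np.arange(n, dtype=float)
        mk = markers if markers is not None else [True] * n
        return LodCurve(pd.DataFrame({"chrom": "c1", "cM": pos,
                                      "lod": lod, "is_marker": mk}), n=100)

    def test_delta_curve_collapses(self):
        lod = np.zeros(21)
        lod[10] = 20.0
        lo, hi = bayes_interval(self._curve(lod), "c1")
        assert lo <= 10 <= hi
        assert hi - lo <= 2

    def test_flat_curve_whole_chromosome(self):
        lo, hi = bayes_interval(self._curve(np.zeros(15)), "c1")
        assert (lo, hi) == (0.0, 14.0)

    def test_interval_contains_argmax(self):
        rng = np.random.default_rng(5)
        lod = rng.uniform(0, 5, size=30)
        lo, hi = bayes_interval(self._curve(lod), "c1")
        assert lo <= float(np.argmax(lod)) <= hi

    def test_summarize_reports_h2_and_flanks(self, f2_chrom):
        gm, truth = f2_chrom
        rng = np.random.default_rng(6)
        y = gm.dosage[:, 12] + 0.5 * rng.normal(size=gm.n_lines)
        curve = sim_scan(gm, y, truth.map, ScanConfig(step_cM=2.0))
        curve.threshold = 3.0
        hits = summarize_qtl(curve)
        assert len(hits) == 1
        h = hits[0]
        assert h.interval[0] <= h.peak_cM <= h.interval[1]
        assert 0 < h.h2_explained < 1
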