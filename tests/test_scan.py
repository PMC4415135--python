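"""Genome-scan mechanics: LOD against a least-squares oracle, permutation
thresholds, FDR, peak calling, support intervals and local/distant rules."""

import numpy as np
import pandas as pd
import pytest

from srnaqtl import scan as sc
from srnaqtl.genome import BinMap


def make_binmap(geno, chrom=None, bin_bp=100_000):
    """BinMap from an (individuals x bins) dosage array."""
    geno = np.asarray(geno, dtype=np.int8)
    n_bins = geno.shape[1]
    if chrom is None:
        chrom = ["chr01"] * n_bins
    rows, pos = [], {}
    for j, c in enumerate(chrom):
        p = pos.get(c, 0)
        rows.append((c, p, p + bin_bp))
        pos[c] = p + bin_bp
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    inds = [f"i{k}" for k in range(geno.shape[0])]
    return BinMap(bins, geno, inds)


@pytest.fixture(scope="module")
def random_design():
    rng = np.random.default_rng(1)
    geno = rng.choice([0, 1, 2], size=(98, 40), p=[0.25, 0.5, 0.25])
    chrom = ["chr01"] * 20 + ["chr02"] * 20
    binmap = make_binmap(geno, chrom)
    return binmap, sc.GenotypeDesign(binmap)


def oracle_lod(y, x, z):
    """Independent least-squares LOD: reduced = intercept, full adds x, z."""
    n = len(y)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), x, z])
    rss0 = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2)
    rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
    return (n / 2) * np.log10(rss0 / rss1)


class TestLOD:
    def test_matches_regression_oracle_small_case(self):
        """n=8, two homozygote groups, near-noise-free contrast."""
        rng = np.random.default_rng(0)
        geno = np.array([[2] * 4 + [0] * 4]).T  # one bin
        binmap = make_binmap(geno)
        design = sc.GenotypeDesign(binmap)
        y = np.array([2, 2, 2, 2, 0, 0, 0, 0]) + rng.normal(0, 0.01, 8)
        prof = sc.scan_trait(y, design)
        x = geno[:, 0].astype(float) - 1
        z = (geno[:, 0] == 1).astype(float)
        assert prof[0] == pytest.approx(oracle_lod(y, x, z), abs=1e-6)

    def test_matches_oracle_across_random_bins(self, random_design):
        binmap, design = random_design
        rng = np.random.default_rng(2)
        y = rng.normal(10, 1, design.n) + design.x[:, 5]
        prof = sc.scan_trait(y, design)
        for j in (0, 5, 17, 33):
            assert prof[j] == pytest.approx(
                oracle_lod(y, design.x[:, j], design.z[:, j]), abs=1e-8
            )

    def test_constant_trait_gives_zero_lod(self, random_design):
        _, design = random_design
        prof = sc.scan_trait(np.full(design.n, 3.0), design)
        assert np.allclose(prof, 0.0)

    def test_affine_invariance(self, random_design):
        _, design = random_design
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, design.n) + 0.8 * design.x[:, 10]
        assert np.allclose(
            sc.scan_trait(y, design), sc.scan_trait(100 + 3 * y, design),
            atol=1e-9,
        )

    def test_lod_nonnegative(self, random_design):
        _, design = random_design
        rng = np.random.default_rng(4)
        for _ in range(5):
            prof = sc.scan_trait(rng.normal(size=design.n), design)
            assert (prof >= 0).all()

    def test_monomorphic_bin_scores_zero(self):
        geno = np.ones((30, 3), dtype=np.int8)
        geno[:, 0] = np.tile([0, 2], 15)
        geno[:, 2] = np.tile([0, 1, 2], 10)
        design = sc.GenotypeDesign(make_binmap(geno))
        rng = np.random.default_rng(5)
        y = rng.normal(size=30) + geno[:, 0]
        prof = sc.scan_trait(y, design)
        assert prof[1] == 0.0
        assert prof[0] > 0


class TestCofactors:
    def test_pure_noise_rarely_selects(self, random_design):
        """BIC penalty: >=90% empty sets under the null at n=98."""
        _, design = random_design
        rng = np.random.default_rng(6)
        empty = sum(
            len(sc.select_cofactors(rng.normal(size=design.n), design)) == 0
            for _ in range(100)
        )
        assert empty >= 90

    def test_deterministic_bin_selected_first(self, random_design):
        _, design = random_design
        y = 5.0 + 2.0 * design.x[:, 12]
        cof = sc.select_cofactors(y, design)
        assert 12 in cof

    def test_max_zero_disables(self, random_design):
        _, design = random_design
        y = 5.0 + 2.0 * design.x[:, 12]
        assert sc.select_cofactors(y, design, max_cofactors=0) == ()

    def test_constant_trait_empty(self, random_design):
        _, design = random_design
        assert sc.select_cofactors(np.full(design.n, 2.0), design) == ()

    def test_cofactor_dropped_within_window(self, random_design):
        """With the signal bin as cofactor, bins inside the exclusion window
        still see the signal; far bins on the same chromosome do not."""
        _, design = random_design
        rng = np.random.default_rng(7)
        y = rng.normal(0, 0.5, design.n) + 2.0 * design.x[:, 5]
        full = sc.scan_trait(y, design, cofactors=(5,), window_bp=300_000)
        assert full[5] > 3  # cofactor dropped at its own bin
        base = sc.scan_trait(y, design)
        assert full[15] < base[15] + 0.5  # signal absorbed far away


class TestPermutation:
    def test_alpha_one_gives_minimum(self, random_design):
        _, design = random_design
        rng = np.random.default_rng(8)
        y = rng.normal(size=design.n)
        bases = sc.build_bases(design)
        thr, _, perm_max = sc.permutation_threshold(
            y, bases, design.n, n_perm=50, alpha=1.0, rng=1
        )
        assert thr == pytest.approx(perm_max.min())

    def test_seed_reproducibility(self, random_design):
        _, design = random_design
        rng = np.random.default_rng(9)
        y = rng.normal(size=design.n)
        bases = sc.build_bases(design)
        t1 = sc.permutation_threshold(y, bases, design.n, 100, 0.05, rng=3)
        t2 = sc.permutation_threshold(y, bases, design.n, 100, 0.05, rng=3)
        assert t1[0] == t2[0] and t1[1] == t2[1]

    def test_null_pvalues_uniform(self, random_design):
        """KS test of permutation p-values under the null."""
        from scipy import stats

        _, design = random_design
        rng = np.random.default_rng(10)
        bases = sc.build_bases(design)
        pvals = []
        for _ in range(150):
            y = rng.normal(size=design.n)
            _, p, _ = sc.permutation_threshold(
                y, bases, design.n, n_perm=150, alpha=0.05, rng=rng
            )
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFDR:
    def test_hand_stepped_bh(self):
        p = pd.Series([0.001, 0.02, 0.04, 0.6], index=list("abcd"))
        rej = sc.fdr_across_traits(p, q=0.05)
        assert rej.tolist() == [True, True, False, False]

    def test_degenerate_all_or_none(self):
        assert not sc.fdr_across_traits(pd.Series([1.0] * 5)).any()
        assert sc.fdr_across_traits(pd.Series([1e-6] * 5)).all()


class TestPeaks:
    def design_1chrom(self, n_bins):
        geno = np.random.default_rng(0).choice([0, 1, 2], size=(20, n_bins))
        return sc.GenotypeDesign(make_binmap(geno))

    def test_two_separated_peaks(self):
        design = self.design_1chrom(6)
        prof = np.array([0, 6, 0, 0, 7, 0], dtype=float)
        assert sc.call_peaks(prof, 5.0, design, min_separation=2) == [1, 4]

    def test_below_threshold_empty(self):
        design = self.design_1chrom(6)
        assert sc.call_peaks(np.full(6, 2.0), 5.0, design) == []

    def test_plateau_takes_lowest_coordinate(self):
        design = self.design_1chrom(6)
        prof = np.array([0, 6, 6, 6, 0, 0], dtype=float)
        assert sc.call_peaks(prof, 5.0, design, min_separation=1) == [1]

    def test_close_maxima_collapse_to_higher(self):
        design = self.design_1chrom(6)
        prof = np.array([0, 6, 5.5, 7, 0, 0], dtype=float)
        assert sc.call_peaks(prof, 5.0, design, min_separation=5) == [3]


class TestSupportInterval:
    def test_stated_rule_by_hand(self):
        design = TestPeaks().design_1chrom(5)
        prof = np.array([1, 3, 5, 3, 1], dtype=float)
        assert sc.support_interval(prof, 2, design, drop=1.5) == (1, 3)

    def test_clipped_at_chromosome_end(self):
        design = TestPeaks().design_1chrom(5)
        prof = np.array([1, 2, 3, 4, 5], dtype=float)
        assert sc.support_interval(prof, 4, design, drop=1.5) == (2, 4)

    def test_widening_drop_never_shrinks(self):
        design = TestPeaks().design_1chrom(9)
        rng = np.random.default_rng(11)
        prof = rng.uniform(0, 6, 9)
        peak = int(np.argmax(prof))
        prev = None
        for drop in (0.5, 1.5, 3.0, 10.0):
            lo, hi = sc.support_interval(prof, peak, design, drop)
            assert lo <= peak <= hi
            if prev is not None:
                assert lo <= prev[0] and hi >= prev[1]
            prev = (lo, hi)


class TestVarianceExplained:
    def test_noise_free_planted_effect_is_one(self, random_design):
        binmap, design = random_design
        g = binmap.genotypes[:, 7]
        y = 4.0 + 1.5 * (g.astype(float) - 1) - 0.5 * (g == 1)
        assert sc.variance_explained(y, g) == pytest.approx(1.0)

    def test_null_traits_near_zero(self, random_design):
        """Null R^2 follows Beta(1, (n-3)/2) at 3 genotype classes, so
        P(R^2 < 0.05) = 1 - 0.95^47.5 ~ 0.91 at n=98."""
        binmap, _ = random_design
        rng = np.random.default_rng(12)
        g = binmap.genotypes[:, 3]
        low = sum(
            sc.variance_explained(rng.normal(size=98), g) < 0.05
            for _ in range(200)
        )
        assert low / 200 >= 0.85

    def test_matches_rss_oracle(self, random_design):
        binmap, _ = random_design
        rng = np.random.default_rng(13)
        g = binmap.genotypes[:, 9]
        y = rng.normal(size=98) + 0.7 * g
        x = g.astype(float) - 1
        z = (g == 1).astype(float)
        X = np.column_stack([np.ones(98), x, z])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = np.sum((y - X @ beta) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert sc.variance_explained(y, g) == pytest.approx(
            1 - rss / tss, abs=1e-10
        )


class TestLocalDistant:
    def test_rules(self, random_design):
        _, design = random_design
        # peak at bin 5 of chr01 (bins are 100 kb); interval bins 4-6
        assert sc.classify_local_distant(
            5, (4, 6), "chr01", 450_000, design
        ) == "local"  # inside interval bp span
        assert sc.classify_local_distant(
            5, (4, 6), "chr02", 450_000, design
        ) == "distant"  # different chromosome
        # anchor 240 kb beyond the peak bin's end -> local via 250-kb rule
        assert sc.classify_local_distant(
            5, (5, 5), "chr01", 600_000 + 240_000 - 1, design
        ) == "local"
        assert sc.classify_local_distant(
            5, (5, 5), "chr01", 600_000 + 250_001, design
        ) == "distant"


class TestModelFit:
    def test_results_surface_and_summary(self, random_design):
        binmap, design = random_design
        rng = np.random.default_rng(14)
        values = pd.DataFrame(
            rng.normal(10, 1, size=(6, 98)),
            index=[f"t{k}" for k in range(6)],
            columns=binmap.individuals,
        )
        values.iloc[0] += 2.0 * design.x[:, 8]
        anchors = pd.DataFrame(
            {"chrom": "chr01", "position": 850_000, "length": 24},
            index=values.index,
        )
        # permutation p-values floor at 1/(n_perm+1); with 6 traits BH at
        # q=0.05 needs that floor below q/m, hence 200 permutations here
        cfg = sc.ScanConfig(n_perm=200, n_perm_dominance=100)
        res = sc.QTLScanModel(values, binmap, cfg, anchors=anchors).fit(seed=5)
        assert res.significant.loc["t0"]
        row = res.qtl_table.set_index("trait_id").loc["t0"]
        assert abs(row["peak_bin"] - 8) <= 1
        assert row["qtl_class"] == "local"
        assert 0 <= row["r2"] <= 1
        assert "QTL genome scan results" in res.summary()

    def test_fit_deterministic_under_seed(self, random_design):
        binmap, design = random_design
        rng = np.random.default_rng(15)
        values = pd.DataFrame(
            rng.normal(10, 1, size=(3, 98)) + 1.5 * design.x[:, [2]].T,
            index=[f"t{k}" for k in range(3)],
            columns=binmap.individuals,
        )
        cfg = sc.ScanConfig(n_perm=80, n_perm_dominance=80)
        r1 = sc.QTLScanModel(values, binmap, cfg).fit(seed=9)
        r2 = sc.QTLScanModel(values, binmap, cfg).fit(seed=9)
        pd.testing.assert_frame_equal(r1.qtl_table, r2.qtl_table)
        pd.testing.assert_series_equal(r1.pvalues, r2.pvalues)
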