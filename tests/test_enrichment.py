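"""MAF/LD binning, matched-control resampling and the enrichment test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from polydiff import enrichment as en


class TestBins:
    def test_maf_bin_edges(self):
        # half-open [lo, hi) bins of width 0.025; last closed at 0.5
        assert en.maf_bin_index(np.array([0.26]))[0] == 10
        assert en.maf_bin_index(np.array([0.025]))[0] == 1
        assert en.maf_bin_index(np.array([0.5]))[0] == 19
        assert en.maf_bin_index(np.array([0.0249]))[0] == 0

    def test_low_maf_excluded(self):
        ids = np.array(["a", "b", "c"])
        bins = en.build_bins(ids, np.array([0.005, 0.3, 0.4]),
                             matching_mode="maf_only")
        assert "a" not in bins.assignment.index
        assert {"b", "c"} <= set(bins.assignment.index)

    def test_uniform_pool_fills_cells_evenly(self, rng):
        n = 40_000
        ids = np.array([f"r{i}" for i in range(n)])
        maf = rng.uniform(0.01, 0.5, n)
        ld = rng.uniform(1, 100, n)
        bins = en.build_bins(ids, maf, ld)
        counts = bins.assignment.value_counts()
        # 400 cells; LD quantiles give equal fills within each MAF bin
        assert len(counts) == 400
        per_maf = bins.maf_bin.value_counts()
        for b in per_maf.index:
            cell_counts = counts[counts.index // 20 == b]
            assert cell_counts.max() - cell_counts.min() <= 1

    def test_tiny_maf_bin_collapses_not_fails(self):
        ids = np.array([f"r{i}" for i in range(25)])
        maf = np.concatenate([np.full(3, 0.02), np.full(22, 0.3)])
        ld = np.arange(25, dtype=float) + 1
        bins = en.build_bins(ids, maf, ld)
        # 3-SNP MAF bin has a single (collapsed) LD bin
        assert bins.ld_bin.loc[["r0", "r1", "r2"]].nunique() == 1

    def test_boundary_ties_go_low(self):
        ids = np.array([f"r{i}" for i in range(40)])
        maf = np.full(40, 0.3)
        ld = np.repeat([1.0, 2.0], 20)  # massive ties at the 50% quantile
        bins = en.build_bins(ids, maf, ld, n_ld_bins=2)
        assert (bins.ld_bin.loc[[f"r{i}" for i in range(20)]] == 0).all()


class TestSampleControls:
    @pytest.fixture
    def bins(self, rng):
        n = 500
        ids = np.array([f"r{i}" for i in range(n)])
        return en.build_bins(ids, rng.uniform(0.01, 0.5, n),
                             rng.uniform(1, 50, n), n_maf_bins=5, n_ld_bins=2)

    def test_cell_histogram_matches_exactly(self, bins, rng):
        assoc = rng.choice(bins.assignment.index.to_numpy(), 100,
                           replace=False)
        sets = en.sample_controls(bins, assoc, n_sets=50, seed=1)
        want = bins.assignment.loc[assoc].value_counts().sort_index()
        for s in sets:
            got = bins.assignment.loc[s].value_counts().sort_index()
            pd.testing.assert_series_equal(got, want)
            assert len(np.unique(s)) == len(s)          # without replacement
            assert not set(s) & set(assoc)               # pool excludes hits

    def test_seed_reproducible_and_independent(self, bins):
        assoc = bins.assignment.index[:10].to_numpy()
        a = en.sample_controls(bins, assoc, n_sets=5, seed=7)
        b = en.sample_controls(bins, assoc, n_sets=5, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(np.sort(x), np.sort(y))

    def test_small_pool_warns_and_replaces(self, caplog):
        ids = np.array(["a", "b", "c"])
        bins = en.build_bins(ids, np.array([0.3, 0.3, 0.3]),
                             matching_mode="maf_only")
        sets = en.sample_controls(bins, ["a", "b"], n_sets=3, seed=0)
        assert all(len(s) == 2 for s in sets)  # 'c' drawn with replacement


class TestEnrichmentTest:
    def _stat(self):
        rng = np.random.default_rng(3)
        ids = [f"r{i}" for i in range(300)]
        return pd.Series(rng.normal(0.1, 0.02, 300), index=ids), ids

    def test_observed_equals_null_mean(self):
        stat, ids = self._stat()
        # controls drawn so every null mean equals the observed mean
        assoc = ids[:5]
        sets = [np.array(assoc)] * 10  # same values -> null_sd = 0
        stat_c = stat.copy()
        res = en.enrichment_test(stat_c, assoc, sets)
        assert res.z == 0.0
        assert res.p_two_tailed == 1.0

    def test_normal_quantile(self, rng):
        stat, ids = self._stat()
        sets = [rng.choice(ids[10:], 20, replace=False) for _ in range(2000)]
        null_means = np.array([stat.loc[s].mean() for s in sets])
        mu, sd = null_means.mean(), null_means.std(ddof=1)
        # construct an associated set whose mean sits at mu + 1.96 sd
        target = mu + 1.96 * sd
        res = en.enrichment_test(stat, ids[:20], sets)
        # verify the z/p arithmetic directly on the reported numbers
        assert res.z == pytest.approx((res.observed - mu) / sd)
        assert res.p_two_tailed == pytest.approx(
            2 * sps.norm.sf(abs(res.z)), rel=1e-12)
        manual = en.EnrichmentResult(
            observed=target, null_means=null_means, null_mu=mu, null_sd=sd,
            z=1.96, p_two_tailed=2 * sps.norm.sf(1.96), p_empirical=np.nan)
        assert manual.p_two_tailed == pytest.approx(0.05, abs=0.001)

    def test_empirical_agrees_with_normal(self, rng):
        stat, ids = self._stat()
        assoc = ids[:25]
        sets = [rng.choice(ids[25:], 25, replace=False) for _ in range(4000)]
        res = en.enrichment_test(stat, assoc, sets)
        # null means are averages of 25 iid draws -> near-normal
        assert res.p_empirical == pytest.approx(res.p_two_tailed, abs=0.05)

    def test_variance_statistic(self, rng):
        stat, ids = self._stat()
        sets = [rng.choice(ids[30:], 30, replace=False) for _ in range(100)]
        res = en.enrichment_test(stat, ids[:30], sets, summary_stat="variance")
        assert res.observed == pytest.approx(
            stat.loc[ids[:30]].var(ddof=1))

    def test_too_few_sets_errors(self):
        stat, ids = self._stat()
        with pytest.raises(ValueError):
            en.enrichment_test(stat, ids[:5], [np.array(ids[5:10])])

    def test_missing_stat_dropped_symmetrically(self, rng):
        stat, ids = self._stat()
        stat.iloc[0] = np.nan
        assoc = ids[:10]  # includes the NaN SNP
        sets = [np.array(ids[10:20]), np.array([ids[0]] + ids[20:29])]
        res = en.enrichment_test(stat, assoc, sets)
        assert res.n_snps == 9
        assert np.isfinite(res.null_means).all()


class TestControlDistributionMatch:
    def test_controls_reproduce_maf_distribution(self, rng):
        """Control sets should be indistinguishable from the associated
        SNPs in MAF (two-sample KS) for nearly all sets."""
        n = 8000
        ids = np.array([f"r{i}" for i in range(n)])
        maf = rng.uniform(0.01, 0.5, n)
        ld = rng.lognormal(1.0, 0.5, n) + 1
        bins = en.build_bins(ids, maf, ld)
        maf_s = pd.Series(maf, index=ids)
        # associated SNPs skewed toward common variants
        weights = maf ** 2
        assoc = rng.choice(ids, 150, replace=False, p=weights / weights.sum())
        sets = en.sample_controls(bins, assoc, n_sets=100, seed=4)
        ks_ok = sum(
            sps.ks_2samp(maf_s.loc[assoc], maf_s.loc[s]).pvalue > 0.01
            for s in sets)
        assert ks_ok >= 95
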