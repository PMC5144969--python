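import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from recphen import (SimConfig, additive_linear_test, build_phenotype_table,
                     call_cohort, hwe_exact_p, qc_filter, qq_lambda, run_gwas,
                     simulate_cohort)
from recphen.association import P_FLOOR, bulk_linear_scan
from recphen.evaluation import _hwe_oracle


class TestHweExact:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 2, 1), 1.0),            # most probable het count
        ((2, 0, 2), 6 / 70),         # extreme het deficit at n=4
        ((100, 0, 0), 1.0),          # monomorphic
        ((0, 0, 50), 1.0),           # monomorphic, other homozygote
    ])
    def test_worked_examples(self, counts, expected):
        assert hwe_exact_p(*counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_exact_enumeration_sampled(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            assert hwe_exact_p(n_aa, n_ab, n_bb) == pytest.approx(
                _hwe_oracle(n_aa, n_ab, n_bb), abs=1e-10)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


@pytest.fixture(scope="module")
def qc_cohort():
    return simulate_cohort(SimConfig(n_families=100, n_markers_per_chrom=300,
                                     maf_range=(0.05, 0.5), seed=21))


class TestQcFilter:
    def test_low_maf_marker_removed(self, qc_cohort):
        genos = qc_cohort.genotypes
        values = genos.values.copy()
        rng = np.random.default_rng(1)
        values[:, 0] = (rng.random(values.shape[0]) < 0.015).astype(np.int8)  # MAF ~1%
        noisy = type(genos)(list(genos.individuals), genos.marker_ids, values)
        keep = qc_filter(noisy, qc_cohort.pedigree)
        assert not keep[0]

    def test_het_deficit_removed(self, qc_cohort):
        genos = qc_cohort.genotypes
        values = genos.values.copy()
        n = values.shape[0]
        values[: n // 2, 1] = 0
        values[n // 2:, 1] = 2  # (50%, 0, 50%): gross HWE violation
        noisy = type(genos)(list(genos.individuals), genos.marker_ids, values)
        keep = qc_filter(noisy, qc_cohort.pedigree)
        assert not keep[1]
        assert hwe_exact_p(len(qc_cohort.pedigree.founders) // 2, 0,
                           len(qc_cohort.pedigree.founders) // 2) < 1e-4

    def test_monotone_in_thresholds(self, qc_cohort):
        base = qc_filter(qc_cohort.genotypes, qc_cohort.pedigree)
        stricter_maf = qc_filter(qc_cohort.genotypes, qc_cohort.pedigree, maf_min=0.1)
        stricter_hwe = qc_filter(qc_cohort.genotypes, qc_cohort.pedigree, hwe_max=0.05)
        assert not np.any(stricter_maf & ~base)
        assert not np.any(stricter_hwe & ~base)


class TestAdditiveLinearTest:
    def test_worked_example(self):
        res = additive_linear_test(np.array([0, 1, 1, 2, 2, 3.0]),
                                   np.array([0, 0, 1, 1, 2, 2.0]))
        assert res.beta == pytest.approx(1.0)
        assert res.se == pytest.approx(0.3062, abs=2e-4)
        assert res.p == pytest.approx(0.0309, abs=2e-3)
        assert res.n == 6

    def test_constant_phenotype_null(self):
        res = additive_linear_test(np.full(10, 3.3), np.tile([0, 1, 2], 4)[:10].astype(float))
        assert res.beta == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_perfect_fit_uses_floor(self):
        g = np.array([0, 0, 1, 1, 2, 2.0])
        res = additive_linear_test(2 * g + 1, g)
        assert res.beta == pytest.approx(2.0)
        assert res.se == 0.0
        assert res.p == P_FLOOR

    def test_degenerate_inputs_missing_stats(self):
        assert np.isnan(additive_linear_test(np.array([1.0, 2]), np.array([0.0, 1])).beta)
        assert np.isnan(additive_linear_test(np.arange(5.0), np.ones(5)).beta)

    def test_missing_values_dropped(self):
        y = np.array([1.0, np.nan, 2, 3, 4, 5, 1])
        g = np.array([0, 1, -1, 1, 2, 2, 0], dtype=float)
        assert additive_linear_test(y, g).n == 5

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_statsmodels(self, seed):
        import statsmodels.api as sm
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        g = rng.integers(0, 3, size=n).astype(float)
        if np.all(g == g[0]):
            g[0] = (g[0] + 1) % 3
        y = rng.normal(size=n) + g
        res = additive_linear_test(y, g)
        fit = sm.OLS(y, sm.add_constant(g)).fit()
        assert res.beta == pytest.approx(fit.params[1], rel=1e-9)
        assert res.se == pytest.approx(fit.bse[1], rel=1e-9)
        assert res.p == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_bulk_scan_matches_scalar(self):
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
        G[rng.random(G.shape) < 0.05] = -1
        y = rng.normal(size=50)
        y[:3] = np.nan
        bulk = bulk_linear_scan(y, G)
        for j in range(30):
            ref = additive_linear_test(y, G[j].astype(float))
            if np.isnan(ref.beta):
                assert np.isnan(bulk["beta"][j])
            else:
                assert bulk["beta"][j] == pytest.approx(ref.beta, rel=1e-12)
                assert bulk["se"][j] == pytest.approx(ref.se, rel=1e-12)
                assert bulk["p"][j] == pytest.approx(ref.p, rel=1e-9)


class TestRunGwas:
    def test_small_stratum_rejected(self, small_cohort):
        events = call_cohort(small_cohort.pedigree, small_cohort.marker_map,
                             small_cohort.genotypes)
        pheno = build_phenotype_table(events, small_cohort.pedigree,
                                      small_cohort.hotspots, small_cohort.motifs)
        with pytest.raises(ValueError, match="stratum"):
            run_gwas(pheno.head(5), small_cohort.genotypes, small_cohort.marker_map,
                     small_cohort.pedigree, "ARC", sex="F", cohort="sim")

    def test_one_record_per_kept_marker(self, clean_cohort):
        events = call_cohort(clean_cohort.pedigree, clean_cohort.marker_map,
                             clean_cohort.genotypes)
        pheno = build_phenotype_table(events, clean_cohort.pedigree,
                                      clean_cohort.hotspots, clean_cohort.motifs)
        keep = qc_filter(clean_cohort.genotypes, clean_cohort.pedigree)
        res = run_gwas(pheno, clean_cohort.genotypes, clean_cohort.marker_map,
                       clean_cohort.pedigree, "ARC", sex="M", cohort="sim", keep=keep)
        assert len(res) == int(keep.sum())
        assert (res["stratum"] == "sim:M").all()
        assert res["n"].max() <= len(clean_cohort.pedigree.families)


class TestQqLambda:
    def test_constant_p_closed_form(self):
        # all p = P(chi2_1 > 1): lambda = 1 / median(chi2_1)
        p = np.full(99, float(stats.chi2.sf(1.0, 1)))
        _, lam = qq_lambda(p)
        assert lam == pytest.approx(1 / 0.4549, abs=2e-3)

    def test_single_p_of_one(self):
        _, lam = qq_lambda([1.0])
        assert lam == 0.0

    def test_uniform_p_calibrated(self):
        rng = np.random.default_rng(7)
        _, lam = qq_lambda(rng.random(100_000))
        assert abs(lam - 1.0) < 0.05

    def test_table_shape_and_orientation(self):
        table, _ = qq_lambda([0.5, 0.01, 0.9])
        assert len(table) == 3
        assert table["observed_neglog10"].iloc[0] == pytest.approx(2.0)


class TestCovariateAdjustment:
    def test_matches_statsmodels_multiple_regression(self):
        import statsmodels.api as sm
        from recphen.association import covariate_linear_test
        rng = np.random.default_rng(11)
        n = 60
        g = rng.integers(0, 3, size=n).astype(float)
        C = rng.normal(size=(2, n))
        y = 0.5 * g + C[0] - 0.3 * C[1] + rng.normal(size=n)
        res = covariate_linear_test(y, g, C)
        X = sm.add_constant(np.column_stack([g, C.T]))
        fit = sm.OLS(y, X).fit()
        assert res.beta == pytest.approx(fit.params[1], rel=1e-9)
        assert res.se == pytest.approx(fit.bse[1], rel=1e-9)
        assert res.p == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_run_gwas_with_noise_covariate(self, clean_cohort):
        """Adjusting for an independent noise covariate leaves the scan
        essentially unchanged (hook wired through, default off)."""
        events = call_cohort(clean_cohort.pedigree, clean_cohort.marker_map,
                             clean_cohort.genotypes)
        pheno = build_phenotype_table(events, clean_cohort.pedigree,
                                      clean_cohort.hotspots, clean_cohort.motifs)
        rng = np.random.default_rng(12)
        pheno = pheno.assign(noise=rng.normal(size=len(pheno)))
        plain = run_gwas(pheno, clean_cohort.genotypes, clean_cohort.marker_map,
                         clean_cohort.pedigree, "ARC", sex="F", cohort="sim")
        adj = run_gwas(pheno, clean_cohort.genotypes, clean_cohort.marker_map,
                       clean_cohort.pedigree, "ARC", sex="F", cohort="sim",
                       covariate_columns=["noise"])
        assert len(adj) == len(plain)
        corr = np.corrcoef(plain["beta"], adj["beta"])[0, 1]
        assert corr > 0.99
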