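"""Dosage score test: QC filtering, residualization, informed/uninformed tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

import onsetgwas as og


def make_panel(dosages, info=None, pos=None):
    dosages = np.asarray(dosages, float)
    m = dosages.shape[0]
    return og.GenotypePanel(
        snps=pd.DataFrame({
            "snp": [f"rs{i}" for i in range(m)],
            "chr": "1",
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "ea": "A", "oa": "G",
            "info": info if info is not None else np.ones(m),
        }),
        dosages=dosages,
    )


class TestQcFilter:
    def test_boundary_convention(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(2, 200)).astype(float)
        panel = make_panel(d, info=[0.29, 0.30])
        kept, counts = og.qc_filter(panel)
        assert kept.snps["snp"].tolist() == ["rs1"]  # info 0.30 retained
        assert counts["removed_info"] == 1

    def test_monomorphic_removed(self):
        panel = make_panel(np.vstack([np.zeros(50), np.ones(50) * 0.8]))
        kept, counts = og.qc_filter(panel)
        assert kept.n_snps == 1
        assert counts["removed_maf"] == 1

    def test_counts_on_constructed_fixture(self):
        # 10 SNPs: 3 fail info (one of them also fails MAF), 2 fail MAF only
        rng = np.random.default_rng(1)
        common = rng.binomial(2, 0.3, size=(10, 400)).astype(float)
        rare = rng.binomial(2, 0.002, size=400).astype(float)
        d = common.copy()
        d[2] = rare  # fails both (info set low below)
        d[7] = rare
        d[8] = rng.binomial(2, 0.005, 400).astype(float)
        info = np.ones(10)
        info[[0, 1, 2]] = 0.1
        panel = make_panel(d, info=info)
        kept, counts = og.qc_filter(panel)
        assert counts["removed_info"] == 3
        assert counts["removed_maf"] == 3
        assert counts["removed_both"] == 1
        assert counts["retained"] == 5
        assert kept.n_snps == 5


class TestResidualize:
    def test_no_covariates_demeans(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(og.residualize(v), v - v.mean())

    def test_exact_linear_gives_zero(self):
        rng = np.random.default_rng(2)
        c = rng.standard_normal(50)
        v = 3.0 * c + 1.0
        assert np.allclose(og.residualize(v, c[:, None]), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(80)
        c = rng.standard_normal(80)
        x = np.column_stack([np.ones(80), c])
        beta = np.linalg.solve(x.T @ x, x.T @ v)
        assert np.allclose(og.residualize(v, c[:, None]), v - x @ beta, atol=1e-10)

    def test_output_orthogonal_to_covariates(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(100)
        c = rng.standard_normal((100, 3))
        res = og.residualize(v, c)
        assert np.all(np.abs(res @ c) < 1e-8)

    def test_collinear_column_named(self):
        rng = np.random.default_rng(5)
        c0 = rng.standard_normal(30)
        cov = np.column_stack([c0, 2.0 * c0])
        with pytest.raises(ValueError, match="column 1"):
            og.residualize(rng.standard_normal(30), cov)


class TestScoreTest:
    def test_perfect_correlation_gives_chisq_n(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0, 2, 100)
        res = og.informed_test(d, 2.0 * d - 1.0)
        assert res.chisq == pytest.approx(100.0, rel=1e-9)
        assert res.p < 1e-20

    def test_constant_response_unestimable(self):
        d = np.array([0.0, 1.0, 2.0, 1.0])
        res = og.informed_test(d, np.ones(4))
        assert res.flag == "unestimable"

    def test_null_chisq_distribution(self):
        rng = np.random.default_rng(7)
        n, m = 2000, 2000
        panel = make_panel(rng.binomial(2, 0.3, size=(m, n)).astype(float))
        y = rng.standard_normal(n)
        status = rng.integers(0, 2, n)
        res = og.association_scan(panel, y, status)
        ks = kstest(res["chisq"], chi2(df=1).cdf)
        assert ks.pvalue > 0.01

    def test_affine_invariance_of_chisq(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 2, 300)
        y = rng.standard_normal(300) + 0.2 * d
        base = og.informed_test(d, y)
        scaled = og.informed_test(d, 3.7 * y + 11.0)
        assert scaled.chisq == pytest.approx(base.chisq, rel=1e-10)

    def test_allele_flip_flips_z_keeps_p(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0, 2, 300)
        y = rng.standard_normal(300) + 0.3 * d
        a = og.informed_test(d, y)
        b = og.informed_test(2.0 - d, y)
        assert b.z == pytest.approx(-a.z, rel=1e-10)
        assert b.p == pytest.approx(a.p, rel=1e-10)

    def test_z_squared_equals_chisq(self):
        rng = np.random.default_rng(10)
        d = rng.uniform(0, 2, 150)
        y = rng.standard_normal(150)
        res = og.informed_test(d, y)
        assert res.z**2 == pytest.approx(res.chisq, abs=1e-9)

    def test_uninformed_matches_cochran_armitage_oracle(self):
        # binary dosage 2x2 table: trend statistic from the contingency counts
        n_cases_exp, n_cases_unexp = 30, 70
        n_ctrl_exp, n_ctrl_unexp = 20, 80
        d = np.concatenate([np.ones(n_cases_exp), np.zeros(n_cases_unexp),
                            np.ones(n_ctrl_exp), np.zeros(n_ctrl_unexp)])
        s = np.concatenate([np.ones(100), np.zeros(100)])
        res = og.uninformed_test(d, s)
        n = 200.0
        r1, r2 = 100.0, 100.0  # cases, controls
        c1 = n_cases_exp + n_ctrl_exp  # exposed column
        # Cochran-Armitage trend with scores {0,1} reduces to
        # N (a*d - b*c)^2 / (r1 r2 c1 c0) for a 2x2 table
        a, b = n_cases_exp, n_cases_unexp
        c, dd = n_ctrl_exp, n_ctrl_unexp
        trend = n * (a * dd - b * c) ** 2 / (r1 * r2 * c1 * (n - c1))
        assert res.chisq == pytest.approx(trend, abs=1e-9)

    def test_informed_equals_uninformed_at_constant_prevalence(self, flat_model):
        rng = np.random.default_rng(11)
        n = 400
        pheno = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "centre": "C1",
            "status": rng.integers(0, 2, n),
            "subtype": "IS",
            "age": rng.uniform(45, 85, n),
        })
        liab = og.assign_liabilities(pheno, flat_model, "IS")
        d = rng.uniform(0, 2, n)
        a = og.informed_test(d, liab)
        b = og.uninformed_test(d, pheno["status"].to_numpy())
        assert a.chisq == pytest.approx(b.chisq, rel=1e-10)

    def test_scan_matches_single_snp_path(self):
        rng = np.random.default_rng(12)
        d = rng.binomial(2, 0.25, size=(5, 200)).astype(float)
        cov = rng.standard_normal((200, 2))
        y = rng.standard_normal(200)
        status = rng.integers(0, 2, 200)
        scan = og.association_scan(make_panel(d), y, status, cov)
        for i in range(5):
            single = og.informed_test(d[i], y, cov)
            assert scan.loc[i, "chisq"] == pytest.approx(single.chisq, rel=1e-9)
            assert scan.loc[i, "beta"] == pytest.approx(single.beta, rel=1e-9)

    def test_missing_dosages_mean_imputed(self):
        d = np.array([[0.0, 1.0, np.nan, 2.0, 1.0, np.nan]])
        filled = np.array([[0.0, 1.0, 1.0, 2.0, 1.0, 1.0]])
        y = np.array([0.1, 0.9, 0.4, 1.7, 1.2, 0.3])
        status = np.array([0, 1, 0, 1, 1, 0])
        scan = og.association_scan(make_panel(d), y, status)
        direct = og.informed_test(filled[0], y)
        assert scan.loc[0, "chisq"] == pytest.approx(direct.chisq, rel=1e-9)


class TestLogisticQuantiles:
    def test_two_by_two_matches_cross_product_oracle(self):
        d = np.concatenate([np.ones(30), np.zeros(70), np.ones(20), np.zeros(80)])
        s = np.concatenate([np.ones(100), np.zeros(100)])
        ages = np.full(200, 60.0)
        tab = og.logistic_or_by_quantile(d, s, ages, [60.0])
        assert tab.loc[0, "or"] == pytest.approx((30 * 80) / (70 * 20), rel=1e-4)

    def test_independent_dosage_or_near_one(self):
        rng = np.random.default_rng(13)
        d = rng.binomial(2, 0.3, 600).astype(float)
        s = rng.integers(0, 2, 600)
        ages = rng.uniform(45, 85, 600)
        tab = og.logistic_or_by_quantile(d, s, ages, [85.0])
        assert tab.loc[0, "ci_low"] < 1.0 < tab.loc[0, "ci_high"]

    def test_complete_separation_flagged(self):
        d = np.concatenate([np.full(20, 2.0), np.zeros(20)])
        s = np.concatenate([np.ones(20), np.zeros(20)])
        ages = np.full(40, 60.0)
        tab = og.logistic_or_by_quantile(d, s, ages, [60.0])
        assert tab.loc[0, "flag"] == "separation"

    def test_stratum_without_cases_raises(self):
        d = np.ones(10)
        s = np.concatenate([np.ones(5), np.zeros(5)])
        ages = np.concatenate([np.full(5, 80.0), np.full(5, 50.0)])
        with pytest.raises(ValueError):
            og.logistic_or_by_quantile(d, s, ages, [40.0])

    def test_or_monotone_under_liability_driven_onset(self):
        # the aggregate causal burden shows a stronger odds ratio in younger
        # onset quantiles; monotonicity across cumulative cuts should hold in
        # a large majority of replicates
        mono = 0
        reps = 20
        for seed in range(reps):
            cfg = og.SimulationConfig(seed=seed, n_centres=1, n_cases=1000,
                                      n_controls=1000, m_snps=20, n_causal=20)
            cohort = og.simulate_cohort(cfg)
            ph = cohort.phenotypes
            g = cohort.true_dosages["C1"][:cfg.n_causal]
            score = g.sum(axis=0)
            score = np.clip((score - score.mean()) / score.std() * 0.5 + 1.0, 0, 2)
            ages = ph["age"].to_numpy()
            status = ph["status"].to_numpy()
            cuts = np.quantile(ages[status == 1], [0.25, 0.5, 0.75, 1.0])
            tab = og.logistic_or_by_quantile(score, status, ages, cuts)
            ors = tab["or"].to_numpy()
            mono += bool(np.all(np.diff(ors) <= 1e-12))
        assert mono >= 0.8 * reps
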