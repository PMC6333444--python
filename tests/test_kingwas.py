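"""Residual phenotype construction, single/combined-parent association,
and correlation-adjusted meta-analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from kinspan import kingwas as kg, simcohort as sc


class TestResidualPhenotype:
    def test_residuals_sum_to_zero_before_scaling(self, null_cohort):
        fa = null_cohort.parent("father")
        phen = kg.fit_residual_phenotype(fa["age"], fa["dead"],
                                         null_cohort.covariates(), "father")
        raw = phen.residuals * phen.prop_dead
        assert abs(raw.sum()) < 1e-6 * len(raw)

    def test_prop_dead_divisor(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(50, 90, 1000)
        dead = rng.random(1000) < 0.6
        phen = kg.fit_residual_phenotype(ages, dead)
        phen_raw = phen.residuals * phen.prop_dead
        # reconstruct: dividing the raw martingale residuals by c = 0.602
        # (say) scales them by exactly 1/c
        np.testing.assert_allclose(phen.residuals, phen_raw / phen.prop_dead)
        assert phen.prop_dead == dead.mean()

    def test_no_deaths_is_an_error(self):
        with pytest.raises(ValueError, match="death"):
            kg.fit_residual_phenotype(np.full(100, 70.0), np.zeros(100, bool))

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(50, 90, 200)
        dead = rng.random(200) < 0.5
        x = rng.normal(size=200)
        with pytest.raises(ValueError, match="rank"):
            kg.fit_residual_phenotype(ages, dead, np.column_stack([x, x]))


class TestSingleParentScan:
    def test_null_pvalues_uniform(self):
        """Dosages orthogonal to the residual: p ~ Uniform(0,1)."""
        rng = np.random.default_rng(2)
        n, m = 2000, 2000
        ages = rng.uniform(50, 95, n)
        dead = rng.random(n) < 0.6
        phen = kg.fit_residual_phenotype(ages, dead)
        dosages = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        rec = kg.gwas_single_parent(phen, dosages)
        ks = stats.kstest(rec["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_matches_statsmodels_ols(self, null_cohort):
        fa = null_cohort.parent("father")
        cov = null_cohort.covariates()
        phen = kg.fit_residual_phenotype(fa["age"], fa["dead"], cov, "father")
        rec = kg.gwas_single_parent(phen, null_cohort.dosages, cov,
                                    null_cohort.snp_ids)
        for j in (0, 3, 7):
            X = sm.add_constant(np.column_stack([null_cohort.dosages[:, j], cov]))
            fit = sm.OLS(phen.residuals, X).fit()
            assert rec["beta1"].iloc[j] == pytest.approx(-2 * fit.params[1], rel=1e-8)
            assert rec["se"].iloc[j] == pytest.approx(2 * fit.bse[1], rel=1e-6)

    def test_duplicated_snp_column_identical(self, null_cohort):
        fa = null_cohort.parent("father")
        cov = null_cohort.covariates()
        phen = kg.fit_residual_phenotype(fa["age"], fa["dead"], cov, "father")
        dup = np.column_stack([null_cohort.dosages[:, 0]] * 2)
        rec = kg.gwas_single_parent(phen, dup, cov, ["a", "b"])
        assert rec.iloc[0]["beta1"] == pytest.approx(rec.iloc[1]["beta1"], rel=1e-10)
        assert rec.iloc[0]["se"] == pytest.approx(rec.iloc[1]["se"], rel=1e-10)

    def test_monomorphic_snp_yields_na_with_warning(self, null_cohort):
        fa = null_cohort.parent("father")
        phen = kg.fit_residual_phenotype(fa["age"], fa["dead"])
        dosages = np.column_stack([null_cohort.dosages[:, 0],
                                   np.zeros(null_cohort.n_subjects)])
        with pytest.warns(UserWarning, match="monomorphic"):
            rec = kg.gwas_single_parent(phen, dosages, snp_ids=["ok", "mono"])
        assert np.isnan(rec.set_index("snpid").loc["mono", "beta1"])
        assert np.isfinite(rec.set_index("snpid").loc["ok", "beta1"])

    def test_missing_dosages_mean_imputed(self, null_cohort):
        fa = null_cohort.parent("father")
        phen = kg.fit_residual_phenotype(fa["age"], fa["dead"])
        d = null_cohort.dosages[:, [0]].copy()
        d_missing = d.copy()
        d_missing[:50] = np.nan
        d_imputed = d.copy()
        d_imputed[:50] = np.nanmean(d_missing)
        a = kg.gwas_single_parent(phen, d_missing)
        b = kg.gwas_single_parent(phen, d_imputed)
        assert a["beta1"].iloc[0] == pytest.approx(b["beta1"].iloc[0])

    def test_protective_allele_recovery(self, effect_cohort, effect_cohort_phenotypes):
        """Doubled, negated slope recovers the simulated carrier lnPR."""
        phen_f, _ = effect_cohort_phenotypes
        cov = effect_cohort.covariates()
        rec = kg.gwas_single_parent(phen_f, effect_cohort.dosages, cov,
                                    effect_cohort.snp_ids).set_index("snpid")
        assert abs(rec.loc["hit", "beta1"] - 0.2) < 1.96 * rec.loc["hit", "se"]
        assert abs(rec.loc["neutral", "beta1"]) < 1.96 * rec.loc["neutral", "se"]


class TestCES:
    def test_identical_parents_equal_doubled_single(self, null_cohort):
        fa = null_cohort.parent("father")
        cov = null_cohort.covariates()
        phen = kg.fit_residual_phenotype(fa["age"], fa["dead"], cov, "father")
        single = kg.gwas_single_parent(phen, null_cohort.dosages, cov,
                                       null_cohort.snp_ids)
        ces = kg.combine_ces(phen, phen, null_cohort.dosages, cov,
                             null_cohort.snp_ids)
        # summing two identical residual vectors doubles the slope, which
        # equals the doubled single-parent estimate: doubling happens
        # exactly once in the pipeline
        np.testing.assert_allclose(ces["beta1"], single["beta1"], rtol=1e-10)

    def test_ces_close_to_adjusted_ivw_of_parents(self, effect_cohort,
                                                  effect_cohort_phenotypes):
        phen_f, phen_m = effect_cohort_phenotypes
        cov = effect_cohort.covariates()
        rec_f = kg.gwas_single_parent(phen_f, effect_cohort.dosages, cov,
                                      effect_cohort.snp_ids)
        rec_m = kg.gwas_single_parent(phen_m, effect_cohort.dosages, cov,
                                      effect_cohort.snp_ids)
        ces = kg.combine_ces(phen_f, phen_m, effect_cohort.dosages, cov,
                             effect_cohort.snp_ids)
        r = float(np.corrcoef(phen_f.residuals, phen_m.residuals)[0, 1])
        ivw = kg.meta_ces_correlated([rec_f, rec_m], r=r)
        for sid in effect_cohort.snp_ids:
            a = ces.set_index("snpid").loc[sid]
            b = ivw.set_index("snpid").loc[sid]
            joint_se = np.hypot(a["se"], b["se"])
            assert abs(a["beta1"] - b["beta1"]) < 1.96 * joint_se

    def test_null_z_rarely_extreme(self):
        cohort = sc.simulate_cohort(
            3000, [sc.SnpSpec(id=f"s{i}", maf=0.05 + 0.002 * i)
                   for i in range(200)], seed=21)
        cov = cohort.covariates()
        fa, mo = cohort.parent("father"), cohort.parent("mother")
        phen_f = kg.fit_residual_phenotype(fa["age"], fa["dead"], cov, "father")
        phen_m = kg.fit_residual_phenotype(mo["age"], mo["dead"], cov, "mother")
        ces = kg.combine_ces(phen_f, phen_m, cohort.dosages, cov, cohort.snp_ids)
        assert (np.abs(ces["z"]) < 3.3).mean() > 0.995

    def test_mismatched_subjects_error(self, effect_cohort_phenotypes):
        phen_f, phen_m = effect_cohort_phenotypes
        import dataclasses
        short = dataclasses.replace(phen_m,
                                    residuals=phen_m.residuals[:-1])
        with pytest.raises(ValueError, match="differ"):
            kg.combine_ces(phen_f, short, np.zeros((10, 1)))


class TestSSE:
    @pytest.mark.parametrize("zf,zm,r,expected", [
        (2.0, 2.0, 0.0, 8.0),
        (3.0, 3.0, 0.1, 2 * 9 / 1.1),
        (0.0, 0.0, 0.5, 0.0),
    ])
    def test_closed_forms(self, zf, zm, r, expected):
        chi2, p = kg.combine_sse(zf, zm, r)
        assert chi2 == pytest.approx(expected, rel=1e-12)
        if expected == 0:
            assert p == 1.0

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            kg.combine_sse(1.0, 1.0, 1.0)

    def test_sse_beats_ces_for_opposite_effects(self):
        """Sexually antagonistic SNP: SSE detects what CES cancels out."""
        snps_f = [sc.SnpSpec(id="x", maf=0.3, beta_carrier=0.3)]
        snps_m = [sc.SnpSpec(id="x", maf=0.3, beta_carrier=-0.3)]
        rng = np.random.default_rng(22)
        dos, gf, gm = sc.simulate_genotypes(8000, snps_f, rng=rng)
        surv_f = sc.simulate_lifespans(gf, gm, snps_f, rho=0.0, frailty_sd=0.0,
                                       rng=rng)
        surv_m = sc.simulate_lifespans(gf, gm, snps_m, rho=0.0, frailty_sd=0.0,
                                       rng=rng)
        phen_f = kg.fit_residual_phenotype(surv_f["father_age"],
                                           surv_f["father_dead"], None, "father")
        phen_m = kg.fit_residual_phenotype(surv_m["mother_age"],
                                           surv_m["mother_dead"], None, "mother")
        rec_f = kg.gwas_single_parent(phen_f, dos, snp_ids=["x"])
        rec_m = kg.gwas_single_parent(phen_m, dos, snp_ids=["x"])
        _, p_sse = kg.combine_sse(rec_f["z"].iloc[0], rec_m["z"].iloc[0], r=0.0)
        ces = kg.combine_ces(phen_f, phen_m, dos, snp_ids=["x"])
        assert p_sse < ces["p"].iloc[0]

    def test_ces_beats_sse_for_common_effects(self, effect_cohort,
                                              effect_cohort_phenotypes):
        phen_f, phen_m = effect_cohort_phenotypes
        cov = effect_cohort.covariates()
        rec_f = kg.gwas_single_parent(phen_f, effect_cohort.dosages, cov,
                                      effect_cohort.snp_ids).set_index("snpid")
        rec_m = kg.gwas_single_parent(phen_m, effect_cohort.dosages, cov,
                                      effect_cohort.snp_ids).set_index("snpid")
        _, p_sse = kg.combine_sse(rec_f.loc["hit", "z"], rec_m.loc["hit", "z"], 0.0)
        ces = kg.combine_ces(phen_f, phen_m, effect_cohort.dosages, cov,
                             effect_cohort.snp_ids).set_index("snpid")
        assert ces.loc["hit", "p"] < p_sse


def _record_table(betas, ses, a1="A", a0="G"):
    n = len(betas)
    return pd.DataFrame({
        "snpid": [f"rs{i}" for i in range(n)], "a1": a1, "a0": a0,
        "freq1": 0.3, "beta1": betas, "se": ses,
    })


class TestMetaCorrelated:
    def test_zero_correlation_is_plain_ivw(self):
        a = _record_table([0.2, 0.1], [0.05, 0.04])
        b = _record_table([0.1, 0.3], [0.10, 0.08])
        out = kg.meta_ces_correlated([a, b], r=0.0).set_index("snpid")
        w1, w2 = 1 / 0.05 ** 2, 1 / 0.10 ** 2
        assert out.loc["rs0", "beta1"] == pytest.approx(
            (w1 * 0.2 + w2 * 0.1) / (w1 + w2))
        assert out.loc["rs0", "se"] == pytest.approx(np.sqrt(1 / (w1 + w2)))

    def test_equal_ses_exact_equals_conservative(self):
        a = _record_table([0.2], [0.05])
        b = _record_table([0.1], [0.05])
        out = kg.meta_ces_correlated([a, b], r=0.1)
        assert out["se_exact"].iloc[0] == pytest.approx(out["se"].iloc[0], rel=1e-12)
        var0 = 1 / (2 / 0.05 ** 2)
        assert out["se"].iloc[0] ** 2 == pytest.approx(var0 * 1.1)

    def test_unequal_ses_exact_factor_and_conservatism(self):
        a = _record_table([0.2], [1.0])
        b = _record_table([0.1], [2.0])
        out = kg.meta_ces_correlated([a, b], r=0.1)
        var0 = 1 / (1 / 1.0 + 1 / 4.0)
        factor = 1 + 2 * 0.1 * 1.0 * 2.0 / (1.0 + 4.0)
        assert factor == pytest.approx(1.08)
        assert out["se_exact"].iloc[0] ** 2 == pytest.approx(var0 * factor)
        assert out["se"].iloc[0] >= out["se_exact"].iloc[0]

    def test_allele_flip_invariance(self):
        a = _record_table([0.2, -0.1], [0.05, 0.04])
        b = _record_table([-0.2, 0.1], [0.05, 0.04], a1="G", a0="A")
        out = kg.meta_ces_correlated([a, b], r=0.0).set_index("snpid")
        assert out.loc["rs0", "beta1"] == pytest.approx(0.2)
        assert out.loc["rs1", "beta1"] == pytest.approx(-0.1)

    def test_flipping_effect_allele_flips_beta_keeps_p(self):
        a = _record_table([0.2], [0.05])
        b = _record_table([0.1], [0.04])
        fwd = kg.meta_ces_correlated([a, b], r=0.1)
        a2 = a.copy(); a2["beta1"] = -a2["beta1"]
        a2[["a1", "a0"]] = a2[["a0", "a1"]].to_numpy()
        b2 = b.copy(); b2["beta1"] = -b2["beta1"]
        b2[["a1", "a0"]] = b2[["a0", "a1"]].to_numpy()
        rev = kg.meta_ces_correlated([a2, b2], r=0.1)
        assert rev["beta1"].iloc[0] == pytest.approx(-fwd["beta1"].iloc[0])
        assert rev["p"].iloc[0] == pytest.approx(fwd["p"].iloc[0])

    def test_single_table_rejected(self):
        with pytest.raises(ValueError):
            kg.meta_ces_correlated([_record_table([0.1], [0.05])], r=0.1)


def test_genome_wide_threshold_constant():
    assert kg.GENOME_WIDE_SIG == 2.5e-8


def test_run_cohort_gwas_modes(null_cohort):
    ces = kg.run_cohort_gwas(null_cohort, mode="ces")
    sse = kg.run_cohort_gwas(null_cohort, mode="sse", r=0.1)
    assert len(ces) == len(null_cohort.snp_ids)
    assert {"chi2", "p"} <= set(sse.columns)
    with pytest.raises(ValueError):
        kg.run_cohort_gwas(null_cohort, mode="bogus")
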