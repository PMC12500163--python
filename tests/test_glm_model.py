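"""GLM core and RoP model: oracle agreement, invariance, estimability."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rop.coding import phasetype_table
from rop.glm import DegenerateDesignError, fit_glm, joint_test
from rop.model import (
    RoPModel,
    build_rop_design,
    estimability_report,
    recessive_cis_test,
    rop_multiallelic_test,
    rop_test,
)
from rop.simulate import hap_freqs_from_ld, sample_cohort

REFS = [(a, b) for a in "Aa" for b in "Bb"]


def _sm_family(name):
    return sm.families.Gaussian() if name == "gaussian" else sm.families.Binomial()


class TestFitGlm:
    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_matches_statsmodels_mle(self, family, balanced_cohort, gaussian_null,
                                     binary_null):
        y = gaussian_null if family == "gaussian" else binary_null
        X = build_rop_design(balanced_cohort)
        mine = fit_glm(X, y, family=family)
        ref = sm.GLM(y, X.to_numpy(), family=_sm_family(family)).fit()
        np.testing.assert_allclose(mine.params, ref.params, atol=1e-8)
        np.testing.assert_allclose(mine.deviance, ref.deviance, rtol=1e-10)
        np.testing.assert_allclose(mine.bse, ref.bse, rtol=1e-6)

    def test_constant_response_gaussian(self, balanced_cohort):
        X = build_rop_design(balanced_cohort)
        fit = fit_glm(X, np.full(len(X), 3.0), family="gaussian")
        coefs = fit.param_series()
        assert abs(coefs["const"] - 3.0) < 1e-10
        assert np.abs(coefs.drop("const")).max() < 1e-8

    def test_binomial_interceptonly_baseline_prevalence(self, rng):
        """A logit intercept of -2 corresponds to prevalence 0.12."""
        from scipy.special import expit

        y = (rng.random(50_000) < expit(-2.0)).astype(float)
        fit = fit_glm(np.ones((len(y), 1)), y, family="binomial", columns=["const"])
        assert round(float(fit.mu[0]), 2) == 0.12

    def test_duplicate_column_aliased_once(self, balanced_cohort, gaussian_null):
        X = build_rop_design(balanced_cohort)
        X["GA_copy"] = X["GA"]
        fit = fit_glm(X, gaussian_null, family="gaussian")
        assert len(fit.aliased) == 1
        assert fit.aliased[0] in ("GA", "GA_copy")


class TestOracleEquivalence:
    """Statistics must match an independent full-vs-reduced refit."""

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_lrt_matches_independent_deviance_comparison(
        self, family, balanced_cohort, gaussian_null, binary_null
    ):
        y = gaussian_null if family == "gaussian" else binary_null
        X = build_rop_design(balanced_cohort)
        cis, trans = rop_test(y, balanced_cohort, family=family)
        fam = _sm_family(family)
        full = sm.GLM(y, X.to_numpy(), family=fam).fit()
        for term, result in (("Pcis", cis), ("Ptrans", trans)):
            red = sm.GLM(y, X.drop(columns=term).to_numpy(), family=fam).fit()
            if family == "gaussian":
                oracle = len(y) * np.log(red.deviance / full.deviance)
            else:
                oracle = red.deviance - full.deviance
            assert abs(result.statistic - oracle) < 1e-8
            assert abs(result.p_value - float(
                __import__("scipy.stats", fromlist=["chi2"]).chi2.sf(oracle, 1)
            )) < 1e-8

    def test_wald_matches_statsmodels_wald(self, balanced_cohort, gaussian_null):
        X = build_rop_design(balanced_cohort)
        cis, _ = rop_test(gaussian_null, balanced_cohort, test_type="wald")
        ref = sm.GLM(gaussian_null, X.to_numpy(), family=sm.families.Gaussian()).fit()
        k = list(X.columns).index("Pcis")
        R = np.zeros((1, X.shape[1]))
        R[0, k] = 1.0
        w = float(ref.wald_test(R, scalar=True).statistic)
        assert abs(cis.statistic - w) < 1e-8

    def test_score_close_to_lrt_large_sample(self, rng):
        H = sample_cohort(hap_freqs_from_ld(0.35, 0.4, 0.2), 4000, rng)
        y = rng.normal(size=4000)
        lrt, _ = rop_test(y, H, test_type="lrt")
        score, _ = rop_test(y, H, test_type="score")
        assert abs(lrt.statistic - score.statistic) < 0.05


class TestReferenceInvariance:
    """Test statistics are identical for any reference-allele coding."""

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    @pytest.mark.parametrize("test_type", ["lrt", "wald", "score"])
    def test_statistics_invariant_across_codings(
        self, family, test_type, balanced_cohort, gaussian_null, binary_null
    ):
        y = gaussian_null if family == "gaussian" else binary_null
        stats_cis, stats_trans = [], []
        for ref in REFS:
            cis, trans = rop_test(
                y, balanced_cohort, family=family, test_type=test_type, ref=ref
            )
            stats_cis.append(cis.statistic)
            stats_trans.append(trans.statistic)
        assert max(stats_cis) - min(stats_cis) < 1e-8
        assert max(stats_trans) - min(stats_trans) < 1e-8

    def test_predicted_values_invariant(self, balanced_cohort, gaussian_null):
        fitted = [
            RoPModel(gaussian_null, balanced_cohort, ref=ref).fit().fittedvalues
            for ref in REFS
        ]
        for f in fitted[1:]:
            np.testing.assert_allclose(f, fitted[0], atol=1e-8)

    def test_phase_coefficient_sign_law(self, rng):
        """A Cis_AB effect appears with equal magnitude under every coding:
        same sign for Cis_ab, opposite sign for Cis_aB and Cis_Ab."""
        H = sample_cohort(hap_freqs_from_ld(0.4, 0.4, 0.0), 20_000, rng)
        pt = phasetype_table(H)
        beta = 0.5
        y = 0.1 * pt["GA"].to_numpy() + beta * pt["Cis_AB"].to_numpy() + rng.normal(
            size=len(pt)
        )
        est = {}
        for ref in REFS:
            res = RoPModel(y, H, ref=ref).fit()
            est[ref], se = res.cis.estimates["Pcis"]
            assert abs(abs(est[ref]) - beta) < 4 * se
        assert est[("a", "b")] == pytest.approx(est[("A", "B")], abs=1e-8)
        assert est[("a", "B")] == pytest.approx(-est[("A", "B")], abs=1e-8)
        assert est[("A", "b")] == pytest.approx(-est[("A", "B")], abs=1e-8)


class TestDegenerateAndEstimability:
    def test_too_few_diplotype_classes_raises(self):
        H = np.zeros((50, 2, 2), dtype=int)
        H[0] = [[1, 0], [0, 0]]  # one Ab/ab among ab/ab
        with pytest.raises(DegenerateDesignError):
            RoPModel(np.zeros(50), H)

    def test_full_rank_cohort_all_estimable(self, balanced_cohort):
        X = build_rop_design(balanced_cohort)
        rep = estimability_report(X)
        assert rep["Pcis"]["estimable"] and rep["Ptrans"]["estimable"]

    def test_absent_cis_haplotype_aliases_with_intercept(self):
        # cohort without any AB haplotype: Cis_AB is the zero column
        haps = [((0, 0), (0, 0))] * 10 + [((1, 0), (0, 0))] * 5 \
            + [((0, 1), (0, 0))] * 5 + [((1, 0), (0, 1))] * 5
        H = np.array([[h1, h2] for h1, h2 in haps])
        X = build_rop_design(H)
        rep = estimability_report(X)
        assert not rep["Pcis"]["estimable"]
        y = np.random.default_rng(0).normal(size=len(H))
        cis, trans = rop_test(y, H)
        assert cis.status == "inestimable"
        assert trans.status == "ok"

    def test_complete_ld_rare_common_aliases_cis_with_genotype(self, rng):
        # D' = 1 with pA < pB: f_Ab = 0, so Cis_AB == GA in the population
        freqs = hap_freqs_from_ld(0.05, 0.25, 1.0)
        assert freqs["Ab"] == pytest.approx(0.0, abs=1e-12)
        H = sample_cohort(freqs, 2000, rng)
        pt = phasetype_table(H)
        assert (pt["Cis_AB"] == pt["GA"]).all()
        rep = estimability_report(build_rop_design(H))
        assert not rep["Pcis"]["estimable"]
        assert "GA" in rep["Pcis"]["aliased_with"]


class TestRecessiveCis:
    def test_dcis_is_indicator_of_single_cis_count(self, balanced_cohort):
        X = build_rop_design(balanced_cohort, dominance_phase=True)
        assert (X["Dcis"] == (X["Pcis"] == 1).astype(float)).all()
        assert (X["Dtrans"] == (X["Ptrans"] == 1).astype(float)).all()

    @pytest.mark.parametrize("variant", [1, 2])
    def test_two_df_joint_test(self, variant, balanced_cohort, gaussian_null):
        res = recessive_cis_test(
            gaussian_null, balanced_cohort, model_variant=variant
        )
        assert res.ok and res.df == 2

    def test_model2_omits_trans_terms(self, balanced_cohort):
        X = build_rop_design(balanced_cohort, dominance_phase=True,
                             include_trans=False)
        assert "Ptrans" not in X.columns and "Dtrans" not in X.columns


class TestMultiallelic:
    def _multi_cohort(self, rng, m, n, size=600):
        from rop.coding import encode_multiallelic

        alleles_a = tuple(f"A{i+1}" for i in range(m))
        alleles_b = tuple(f"B{j+1}" for j in range(n))
        codes = []
        for _ in range(size):
            h1 = (rng.choice(alleles_a), rng.choice(alleles_b))
            h2 = (rng.choice(alleles_a), rng.choice(alleles_b))
            codes.append(encode_multiallelic(h1, h2, alleles_a, alleles_b))
        return codes

    def test_biallelic_reduction_equals_rop_test(self, rng, balanced_cohort,
                                                 gaussian_null):
        from rop.coding import encode_multiallelic

        codes = []
        for h1, h2 in balanced_cohort[:, :, :].tolist():
            lab = lambda h: ("A" if h[0] else "a", "B" if h[1] else "b")
            codes.append(
                encode_multiallelic(lab(h1), lab(h2), ("a", "A"), ("b", "B"))
            )
        cis_m, trans_m = rop_multiallelic_test(gaussian_null, codes)
        cis, trans = rop_test(gaussian_null, balanced_cohort)
        assert cis_m.df == 1 and trans_m.df == 1
        assert cis_m.statistic == pytest.approx(cis.statistic, abs=1e-8)
        assert trans_m.statistic == pytest.approx(trans.statistic, abs=1e-8)

    @pytest.mark.parametrize("m,n,df", [(3, 2, 2), (3, 3, 4)])
    def test_joint_df_is_m1_by_n1(self, rng, m, n, df):
        codes = self._multi_cohort(rng, m, n)
        y = rng.normal(size=len(codes))
        cis, trans = rop_multiallelic_test(y, codes)
        assert cis.df == df and trans.df == df

    def test_statistic_matches_statsmodels_refit(self, rng):
        from rop.coding import multiallelic_design

        codes = self._multi_cohort(rng, 3, 3)
        y = rng.normal(size=len(codes))
        cis, _ = rop_multiallelic_test(y, codes)
        D = multiallelic_design(codes)
        X = np.column_stack([np.ones(len(D)), D.to_numpy()])
        cis_idx = [1 + i for i, c in enumerate(D.columns) if c.startswith("Cis[")]
        full = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
        red = sm.GLM(y, np.delete(X, cis_idx, axis=1),
                     family=sm.families.Gaussian()).fit()
        oracle = len(y) * np.log(red.deviance / full.deviance)
        assert cis.statistic == pytest.approx(oracle, abs=1e-8)


def test_gaussian_f_inference_option(balanced_cohort, gaussian_null):
    cis_chi, _ = rop_test(gaussian_null, balanced_cohort)
    cis_f, _ = rop_test(gaussian_null, balanced_cohort, inference="f")
    # F and chi-square p-values agree closely at n = 400
    assert abs(cis_f.p_value - cis_chi.p_value) < 0.01


def test_summary_contains_tests_and_terms(balanced_cohort, gaussian_null):
    res = RoPModel(gaussian_null, balanced_cohort).fit()
    text = res.summary()
    for token in ("Pcis", "Ptrans", "RoP cis", "RoP trans", "gaussian"):
        assert token in text
    frame = res.to_frame()
    assert set(frame["test"]) == {"RoP cis", "RoP trans"}
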