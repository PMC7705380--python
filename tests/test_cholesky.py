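import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from twinpath import (
    CholeskyParams,
    assumption_tests,
    compare_models,
    decompose,
    expected_covariance,
    fiml_minus2ll,
    fit_model,
    standardize,
    summarize_pairs,
)
from twinpath.cholesky import _make_objective, _unpack

from conftest import AE_TRUTH, make_pair_table


class TestExpectedCovariance:
    def test_ae_sharing_algebra(self):
        p = CholeskyParams(a11=0.8, e11=0.6, e22=1.0)
        mz = expected_covariance(p, "MZ")
        dz = expected_covariance(p, "DZ")
        sib = expected_covariance(p, "NotTwin")
        assert mz[0, 0] == pytest.approx(1.0)
        assert mz[0, 2] == pytest.approx(0.64)
        assert dz[0, 2] == pytest.approx(0.32)
        assert sib[0, 2] == pytest.approx(0.32)

    def test_twin_specific_environment_sharing(self):
        p = CholeskyParams(t11=0.5, e11=0.5, e22=1.0)
        assert expected_covariance(p, "MZ")[0, 2] == pytest.approx(0.25)
        assert expected_covariance(p, "DZ")[0, 2] == pytest.approx(0.25)
        assert expected_covariance(p, "NotTwin")[0, 2] == pytest.approx(0.0)
        # T still contributes within-person variance for non-twins
        assert expected_covariance(p, "NotTwin")[0, 0] == pytest.approx(0.5)

    def test_zero_cross_loadings_zero_cross_trait_cov(self):
        p = CholeskyParams(a11=0.8, a22=0.7, c11=0.2, c22=0.2, e11=0.5, e22=0.5)
        for ptype in ("MZ", "DZ", "NotTwin"):
            sigma = expected_covariance(p, ptype)
            assert sigma[0, 1] == 0.0 and sigma[0, 3] == 0.0 and sigma[2, 1] == 0.0

    def test_symmetric_psd(self):
        sigma = expected_covariance(AE_TRUTH, "DZ")
        np.testing.assert_allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() > 0


class TestFimlObjective:
    def test_single_pair_at_mean_identity_covariance(self):
        p = CholeskyParams(e11=1.0, e22=1.0)
        pairs = pd.DataFrame([
            {"family_id": "f", "pair_type": "NotTwin",
             "sib1_trait1": 0.0, "sib1_trait2": 0.0,
             "sib2_trait1": 0.0, "sib2_trait2": 0.0}
        ])
        assert fiml_minus2ll(p, np.zeros(2), pairs) == pytest.approx(4 * np.log(2 * np.pi))

    def test_doubling_data_doubles_m2ll(self, ae_pairs):
        single = fiml_minus2ll(AE_TRUTH, np.zeros(2), ae_pairs)
        doubled = fiml_minus2ll(AE_TRUTH, np.zeros(2), pd.concat([ae_pairs, ae_pairs]))
        assert doubled == pytest.approx(2 * single, rel=1e-12)

    def test_matches_brute_force_mvn(self):
        """Sufficient-statistic FIML vs per-observation density (independent oracle)."""
        rng = np.random.default_rng(5)
        pairs = make_pair_table(AE_TRUTH, 4, 3, 3, rng)
        means = np.array([0.13, -0.21])
        mu4 = np.array([means[0], means[1], means[0], means[1]])
        brute = 0.0
        for _, row in pairs.iterrows():
            sigma = expected_covariance(AE_TRUTH, row["pair_type"])
            x = row[["sib1_trait1", "sib1_trait2", "sib2_trait1", "sib2_trait2"]].to_numpy(float)
            d = x - mu4
            inv = np.linalg.inv(sigma)
            _, logdet = np.linalg.slogdet(sigma)
            brute += 4 * np.log(2 * np.pi) + logdet + d @ inv @ d
            # cross-check the hand-rolled density against scipy's
            assert -2 * multivariate_normal.logpdf(x, mu4, sigma) == pytest.approx(
                4 * np.log(2 * np.pi) + logdet + d @ inv @ d
            )
        ours = fiml_minus2ll(AE_TRUTH, means, pairs)
        assert ours == pytest.approx(brute, rel=1e-10)

    def test_fast_path_agrees_with_reference(self, ae_pairs):
        summary = summarize_pairs(ae_pairs)
        obj = _make_objective(summary, ("A", "E"), True)
        rng = np.random.default_rng(6)
        for _ in range(5):
            theta = rng.uniform(0.3, 0.9, 8)
            est, mu = _unpack(theta, ("A", "E"), True)
            assert obj(theta) == pytest.approx(fiml_minus2ll(est, mu, summary), rel=1e-10)

    def test_nonpd_gives_inf(self):
        summary = summarize_pairs(
            make_pair_table(AE_TRUTH, 5, 5, 5, np.random.default_rng(7))
        )
        obj = _make_objective(summary, ("A", "E"), False)
        assert obj(np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])) == np.inf  # e22=0


class TestFitModel:
    def test_ae_recovery_within_3_se(self, ae_pairs):
        fit = fit_model(ae_pairs, sources=("A", "E"), seed=1)
        assert fit.converged
        truth = {"a11": 0.8, "a21": -0.3, "a22": 0.7,
                 "e11": 0.6, "e21": -0.1, "e22": 0.65}
        se = dict(zip(fit.param_names, np.sqrt(np.diag(fit.param_cov))))
        for name, true_val in truth.items():
            est = getattr(fit.estimates, name)
            assert abs(est - true_val) < 3 * se[name], name

    def test_e_mandatory(self, ae_pairs):
        with pytest.raises(ValueError, match="E"):
            fit_model(ae_pairs, sources=("A",))

    def test_exchangeability_under_equal_means(self, ae_pairs):
        swapped = ae_pairs.rename(
            columns={"sib1_trait1": "sib2_trait1", "sib2_trait1": "sib1_trait1",
                     "sib1_trait2": "sib2_trait2", "sib2_trait2": "sib1_trait2"}
        )
        a = fit_model(ae_pairs, sources=("A", "E"), seed=1, compute_cov=False)
        b = fit_model(swapped, sources=("A", "E"), seed=1, compute_cov=False)
        assert a.minus2ll == pytest.approx(b.minus2ll, abs=1e-6)

    def test_null_a_boundary_and_lrt_level(self):
        """With no genetic variance the A loading sits at zero and the
        AE-vs-E likelihood-ratio test rejects at no more than nominal rate."""
        rng = np.random.default_rng(8)
        null = CholeskyParams(e11=1.0, e22=1.0)
        rejections = 0
        a11s = []
        n_rep = 30
        for _ in range(n_rep):
            pairs = make_pair_table(null, 100, 100, 100, rng)
            summary = summarize_pairs(pairs)
            ae = fit_model(summary, sources=("A", "E"), seed=2, compute_cov=False, n_starts=3)
            e = fit_model(summary, sources=("E",), seed=2, compute_cov=False, n_starts=3)
            cmp = compare_models(ae, e)
            rejections += cmp["p"] < 0.05
            a11s.append(abs(ae.estimates.a11))
        # genetic variance share a11^2 collapses toward its zero boundary;
        # |a11| itself carries sqrt-scale sampling noise at 300 pairs
        assert np.median(np.square(a11s)) < 0.15
        assert rejections <= 6  # binomial(30, 0.05) upper tail allowance

    def test_aic_penalty(self, ae_pairs):
        fit = fit_model(ae_pairs, sources=("A", "E"), seed=1, compute_cov=False)
        assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.n_free)

    def test_nesting_monotonicity(self, ae_pairs):
        summary = summarize_pairs(ae_pairs)
        at = assumption_tests(summary)
        sat, eqo, eqz = at["minus2ll"]
        actwe = fit_model(summary, sources=("A", "C", "Tw", "E"), seed=1,
                          compute_cov=False).minus2ll
        ae = fit_model(summary, sources=("A", "E"), seed=1, compute_cov=False).minus2ll
        tol = 1e-4
        assert sat <= eqo + tol <= eqz + 2 * tol <= actwe + 3 * tol <= ae + 4 * tol


class TestAssumptionTests:
    def test_nesting_deltas_nonnegative(self, ae_pairs):
        at = assumption_tests(ae_pairs)
        assert (at["delta_m2ll"].dropna() >= 0).all()
        assert at["n_free"].tolist() == [42, 24, 14]

    def test_null_pvalues_uniform(self):
        """LRT p-values under data satisfying every equality assumption."""
        rng = np.random.default_rng(9)
        p_order, p_zyg = [], []
        for _ in range(120):
            pairs = make_pair_table(AE_TRUTH, 80, 80, 80, rng)
            at = assumption_tests(pairs)
            p_order.append(at.loc[1, "p_value"])
            p_zyg.append(at.loc[2, "p_value"])
        assert stats.kstest(p_order, "uniform").pvalue > 0.01
        assert stats.kstest(p_zyg, "uniform").pvalue > 0.01

    def test_power_against_mz_mean_shift(self):
        rng = np.random.default_rng(10)
        rejected = 0
        for _ in range(10):
            pairs = make_pair_table(AE_TRUTH, 100, 100, 100, rng)
            mz = pairs["pair_type"] == "MZ"
            for col in ("sib1_trait1", "sib2_trait1"):
                pairs.loc[mz, col] += 2.0  # 2 SD shift in the MZ group only
            at = assumption_tests(pairs)
            rejected += at.loc[2, "p_value"] < 0.05
        assert rejected == 10

    def test_needs_two_groups(self):
        pairs = make_pair_table(AE_TRUTH, 50, 0, 0, np.random.default_rng(11))
        with pytest.raises(ValueError, match="groups"):
            assumption_tests(pairs)


class TestCompareModels:
    def test_identical_models(self, ae_pairs):
        fit = fit_model(ae_pairs, sources=("A", "E"), seed=1, compute_cov=False)
        cmp = compare_models(fit, fit)
        assert cmp["delta_m2ll"] == 0.0 and cmp["p"] == 1.0

    def test_textbook_chi2(self):
        assert stats.chi2.sf(5.99, 2) == pytest.approx(0.05, abs=1e-3)

    def test_inconsistent_fits_raise(self, ae_pairs):
        parent = fit_model(ae_pairs, sources=("A", "C", "Tw", "E"), seed=1, compute_cov=False)
        child = fit_model(ae_pairs, sources=("A", "E"), seed=1, compute_cov=False)
        broken = type(parent)(
            model_name=parent.model_name, sources=parent.sources,
            estimates=parent.estimates, means=parent.means,
            minus2ll=child.minus2ll + 50.0, n_free=parent.n_free,
            aic=parent.aic, n_pairs=parent.n_pairs, converged=True,
            grad_norm=0.0,
        )
        with pytest.raises(RuntimeError, match="optimizer"):
            compare_models(broken, child)


class TestStandardize:
    def test_unit_variance_ae(self, ae_pairs):
        # a11 = 0.8, e11 = 0.6 -> total variance 1, standardized a11 = 0.8
        fit = fit_model(ae_pairs, sources=("A", "E"), seed=1)
        std = standardize(fit).set_index("path")["standardized"]
        total1 = fit.estimates.a11**2 + fit.estimates.e11**2
        assert std["a11"] == pytest.approx(fit.estimates.a11 / np.sqrt(total1))

    def test_scale_invariance(self, ae_pairs):
        scaled = ae_pairs.copy()
        for c in ("sib1_trait1", "sib1_trait2", "sib2_trait1", "sib2_trait2"):
            scaled[c] = 10.0 * scaled[c]
        a = standardize(fit_model(ae_pairs, sources=("A", "E"), seed=1))
        b = standardize(fit_model(scaled, sources=("A", "E"), seed=1))
        np.testing.assert_allclose(a["standardized"], b["standardized"], atol=1e-5)

    def test_squares_sum_to_one(self, ae_pairs):
        fit = fit_model(ae_pairs, sources=("A", "E"), seed=1)
        std = standardize(fit).set_index("path")["standardized"]
        assert std["a11"] ** 2 + std["e11"] ** 2 == pytest.approx(1.0)
        assert (std["a21"] ** 2 + std["a22"] ** 2
                + std["e21"] ** 2 + std["e22"] ** 2) == pytest.approx(1.0)

    def test_ci_contains_point(self, ae_pairs):
        std = standardize(fit_model(ae_pairs, sources=("A", "E"), seed=1))
        assert (std["ci_low"] <= std["standardized"]).all()
        assert (std["ci_high"] >= std["standardized"]).all()


class TestDecompose:
    def _exact_fit(self, params, sources=("A", "E")):
        from twinpath.cholesky import TwinFit

        return TwinFit(model_name="AE", sources=sources, estimates=params,
                       means=np.zeros(2), minus2ll=0.0, n_free=0, aic=0.0,
                       n_pairs=0, converged=True, grad_norm=0.0)

    def test_worked_example(self):
        """Hand evaluation of the variance/correlation partition formulas."""
        dec = decompose(self._exact_fit(AE_TRUTH))
        assert dec.variance_share_trait1["A"] == pytest.approx(0.64)
        assert dec.covariance["A"] == pytest.approx(-0.24)
        assert dec.covariance["E"] == pytest.approx(-0.06)
        assert dec.total_correlation == pytest.approx(-0.2981, abs=5e-5)
        assert dec.correlation_component["A"] == pytest.approx(-0.2385, abs=5e-5)

    def test_zero_cross_loadings(self):
        p = CholeskyParams(a11=0.8, a22=0.7, e11=0.6, e22=0.65)
        dec = decompose(self._exact_fit(p))
        assert all(v == pytest.approx(0.0) for v in dec.correlation_component.values())

    def test_conservation_identities(self, ae_pairs):
        fit = fit_model(ae_pairs, sources=("A", "E"), seed=1, compute_cov=False)
        dec = decompose(fit)
        assert sum(dec.variance_share_trait1.values()) == pytest.approx(1.0, abs=1e-10)
        assert sum(dec.variance_share_trait2.values()) == pytest.approx(1.0, abs=1e-10)
        sigma = expected_covariance(fit.estimates, "MZ")
        implied_corr = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert sum(dec.correlation_component.values()) == pytest.approx(
            implied_corr, abs=1e-10
        )
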