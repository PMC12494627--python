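import numpy as np
import pytest
from scipy.stats import chi2

import sweetwin as sw
from sweetwin.data import pairs_from_values
from sweetwin.univariate import (
    FitResult,
    LRTResult,
    VarianceComponents,
    compare_models,
    fit_saturated,
)
from sweetwin.univariate import test_assumptions as assumption_checks
from sweetwin._profile import profile_interval


def _ae_pairs(rng, n_mz=2000, n_dz=2000, a=0.6, e=0.4, mean=0.0):
    spec = sw.SimulationSpec(
        n_pairs={"MZ": n_mz, "DZ_SS": n_dz},
        traits={"y": sw.TraitSpec(A=a, E=e, intercept=mean)},
    )
    co = sw.simulate_cohort(spec, rng=rng)
    return sw.pair_wide(co, "y")


class TestExpectedPairCovariance:
    def test_ace_mz(self):
        vc = VarianceComponents(A=1, C=0, E=1, parameterization="ACE")
        assert np.allclose(sw.expected_pair_covariance(vc, "MZ"),
                           [[2, 1], [1, 2]])

    def test_ace_dz(self):
        vc = VarianceComponents(A=1, C=0, E=1, parameterization="ACE")
        assert np.allclose(sw.expected_pair_covariance(vc, "DZ_SS"),
                           [[2, 0.5], [0.5, 2]])

    def test_ade_dz_quarter_weight(self):
        vc = VarianceComponents(A=0.4, D=0.2, E=0.4, parameterization="ADE")
        cov = sw.expected_pair_covariance(vc, "DZ_OS")
        assert cov[0, 1] == pytest.approx(0.4 * 0.5 + 0.2 * 0.25)


class TestSaturated:
    def test_free_parameter_counts(self, rng):
        pt = _ae_pairs(rng, 80, 80)
        assert fit_saturated(pt).n_free == 10

    def test_parameter_count_with_covariates(self, uk_pairs):
        assert fit_saturated(uk_pairs, covariates=("age", "sex")).n_free == 12

    def test_saturated_dominates_restricted_chain(self, rng):
        pt = _ae_pairs(rng, 120, 120)
        sat = fit_saturated(pt)
        lrts = assumption_checks(pt)
        assert len(lrts) == 4
        # chain of nested models: every statistic is non-negative
        assert all(l.statistic >= 0 for l in lrts)
        assert [l.df for l in lrts] == [2, 2, 1, 1]
        ae = sw.fit_continuous(pt, "AE")
        assert sat.loglik >= ae.loglik - 1e-6

    def test_twin_order_mean_shift_detected(self, rng):
        pt = _ae_pairs(rng, 100, 100)
        f = pt.frame.copy()
        f["y_1"] = f["y_1"] + 2.0  # two SDs on a unit-variance trait
        shifted = type(pt)(f, pt.traits, pt.covariates)
        lrts = assumption_checks(shifted)
        assert lrts[0].label.startswith("equal means across twin order")
        assert lrts[0].p < 1e-6


class TestFitContinuous:
    def test_parameter_recovery(self, rng):
        pt = _ae_pairs(rng, 5000, 5000, a=0.6, e=0.4)
        h = sw.heritability(sw.fit_continuous(pt, "AE"))
        assert h["h2"] == pytest.approx(0.60, abs=0.02)
        assert h["total"] == pytest.approx(1.0, abs=0.05)

    def test_e_only_truth_gives_near_zero_a(self, rng):
        pt = _ae_pairs(rng, 1500, 1500, a=0.0, e=1.0)
        fit = sw.fit_continuous(pt, "AE")
        # direct symmetric: A may be slightly negative, never bounded at 0
        assert abs(fit.params["A"]) < 0.08

    def test_nesting_of_logliks(self, rng):
        pt = _ae_pairs(rng, 300, 300)
        ll = {m: sw.fit_continuous(pt, m).loglik for m in ("ACE", "AE", "E")}
        assert ll["ACE"] >= ll["AE"] - 1e-6 >= ll["E"] - 2e-6

    @pytest.mark.parametrize("k", [0.5, 10.0])
    def test_scale_equivariance(self, rng, k):
        pt = _ae_pairs(rng, 400, 400)
        fit1 = sw.fit_continuous(pt, "AE")
        f = pt.frame.copy()
        f[["y_1", "y_2"]] *= k
        fit2 = sw.fit_continuous(type(pt)(f, pt.traits, pt.covariates), "AE")
        assert fit2.params["A"] == pytest.approx(k * k * fit1.params["A"],
                                                 rel=1e-3)
        assert sw.heritability(fit2)["h2"] == pytest.approx(
            sw.heritability(fit1)["h2"], abs=1e-4
        )

    def test_moment_oracle_agreement(self, rng):
        # population-moment (weighted least squares) oracle for the two-group
        # AE estimate: h2 ~= (n_mz*r_mz + 0.5*n_dz*r_dz) / (n_mz + 0.25*n_dz)
        n_mz, n_dz = 244, 250
        mz = sw.simulate_pair_values(n_mz * 40, 1.0, 0.50, rng)
        dz = sw.simulate_pair_values(n_dz * 40, 1.0, 0.21, rng)
        pt = pairs_from_values("y", {"MZ": mz, "DZ_SS": dz})
        h2 = sw.heritability(sw.fit_continuous(pt, "AE"))["h2"]
        oracle = (n_mz * 0.50 + 0.5 * n_dz * 0.21) / (n_mz + 0.25 * n_dz)
        assert oracle == pytest.approx(0.4837, abs=1e-4)
        assert h2 == pytest.approx(oracle, abs=0.02)

    def test_grid_oracle_never_beats_optimizer(self, rng):
        pt = _ae_pairs(rng, 200, 200)
        fit = sw.fit_continuous(pt, "AE")
        obj = fit._objective
        mu = fit.params["mu"]
        best = -fit.loglik
        for a in np.linspace(-0.3, 1.5, 40):
            for e in np.linspace(0.05, 2.0, 40):
                nll = obj.negloglik(np.array([mu, a, e]))
                assert nll >= best - 1e-4


class TestFitOrdinal:
    def test_threshold_recovery(self, rng):
        cuts = sw.thresholds_from_proportions((0.42, 0.22, 0.36))
        vals = sw.simulate_pair_values(5000, 1.0, 0.44, rng)
        codes = np.digitize(vals, cuts.as_tuple()).astype(float)
        pt = pairs_from_values("s", {"MZ": codes})
        pt2 = pairs_from_values(
            "s",
            {"MZ": codes,
             "DZ_SS": np.digitize(
                 sw.simulate_pair_values(5000, 1.0, 0.22, rng), cuts.as_tuple()
             ).astype(float)},
        )
        fit = sw.fit_ordinal(pt2, "AE")
        assert fit.params["tau1"] == pytest.approx(cuts.tau1, abs=0.05)
        assert fit.params["tau2"] == pytest.approx(cuts.tau2, abs=0.05)
        assert fit.params["A"] == pytest.approx(0.44, abs=0.06)

    def test_zero_heritability_centered_on_zero(self, rng):
        vals_mz = np.digitize(sw.simulate_pair_values(3000, 1.0, 0.0, rng),
                              [-0.4, 0.4]).astype(float)
        vals_dz = np.digitize(sw.simulate_pair_values(3000, 1.0, 0.0, rng),
                              [-0.4, 0.4]).astype(float)
        pt = pairs_from_values("s", {"MZ": vals_mz, "DZ_SS": vals_dz})
        assert abs(sw.fit_ordinal(pt, "AE").params["A"]) < 0.1

    def test_continuous_and_ordinal_agree(self, uk_cohort):
        pt_c = sw.pair_wide(uk_cohort, "liking")
        pt_o = sw.pair_wide(uk_cohort, "sweet_status")
        h_c = sw.heritability(sw.fit_continuous(pt_c, "AE"))["h2"]
        h_o = sw.fit_ordinal(pt_o, "AE").params["A"]
        assert h_o == pytest.approx(h_c, abs=0.15)

    def test_empty_category_error(self):
        pt = pairs_from_values("s", {"MZ": np.ones((30, 2))})
        with pytest.raises(ValueError, match="categor"):
            sw.fit_ordinal(pt, "AE")


class TestCompareModels:
    def _fit(self, ll, k):
        return FitResult(loglik=ll, model="x", kind="continuous", params={},
                         n_free=k, converged=True, gradient_norm=0.0,
                         n_complete=0, n_single=0)

    def test_chi_square_tail_oracle(self):
        res = compare_models(self._fit(-1000.0, 3), self._fit(-1002.5, 2))
        assert res.statistic == pytest.approx(5.0)
        assert res.p == pytest.approx(chi2.sf(5.0, 1), abs=1e-12)
        assert res.p == pytest.approx(0.0253, abs=2e-4)

    def test_identical_fits(self):
        res = compare_models(self._fit(-50.0, 2), self._fit(-50.0, 1))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="not nested"):
            compare_models(self._fit(-60.0, 2), self._fit(-50.0, 1))

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            compare_models(self._fit(-50.0, 2), self._fit(-51.0, 2))


class TestHeritability:
    def test_published_uk_arithmetic(self):
        fit = FitResult(loglik=0, model="AE", kind="continuous",
                        params={"A": 184.6, "E": 200.0}, n_free=3,
                        converged=True, gradient_norm=0, n_complete=0,
                        n_single=0)
        h = sw.heritability(fit)
        assert h["h2"] == pytest.approx(0.48, abs=0.002)
        assert h["total"] == pytest.approx(384.6)

    def test_zero_a(self):
        fit = FitResult(loglik=0, model="AE", kind="continuous",
                        params={"A": 0.0, "E": 2.0}, n_free=3, converged=True,
                        gradient_norm=0, n_complete=0, n_single=0)
        assert sw.heritability(fit)["h2"] == 0.0

    def test_shares_sum_to_one(self, rng):
        pt = _ae_pairs(rng, 150, 150)
        h = sw.heritability(sw.fit_continuous(pt, "AE"))
        assert h["h2"] + h["e2"] == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_total_error(self):
        fit = FitResult(loglik=0, model="AE", kind="continuous",
                        params={"A": 1.0, "E": -2.0}, n_free=3, converged=True,
                        gradient_norm=0, n_complete=0, n_single=0)
        with pytest.raises(ValueError):
            sw.heritability(fit)


class TestProfileCI:
    def test_gaussian_mean_toy_matches_wald(self):
        # known-variance normal mean: profile CI must equal the Wald CI
        n, xbar, sigma = 25, 1.3, 2.0

        def nll(theta):
            return 0.5 * n * (theta[0] - xbar) ** 2 / sigma**2

        ci = profile_interval(nll, np.array([xbar]), lambda th: th[0])
        hw = 1.959963985 * sigma / np.sqrt(n)
        assert ci.lower == pytest.approx(xbar - hw, abs=1e-4)
        assert ci.upper == pytest.approx(xbar + hw, abs=1e-4)

    def test_ci_contains_estimate(self, rng):
        pt = _ae_pairs(rng, 250, 250)
        fit = sw.fit_continuous(pt, "AE")
        ci = sw.profile_ci(fit, "h2")
        assert ci.lower < sw.heritability(fit)["h2"] < ci.upper

    def test_total_variance_ci_brackets_truth(self, rng):
        pt = _ae_pairs(rng, 800, 800)
        fit = sw.fit_continuous(pt, "AE")
        ci = sw.profile_ci(fit, "total")
        assert ci.lower < 1.0 < ci.upper  # generating total variance
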