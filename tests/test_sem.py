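"""SEM estimation: discrepancy function, closed-form oracles, brute-force
cross-check, factor scores, sex-anchored rescaling, weighted covariance."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from gendersem.dag import SemSpecification
from gendersem.sem import (
    factor_scores,
    fit_indices,
    fit_sem,
    ml_discrepancy,
    model_implied_covariance,
    rescale_gender,
    weighted_covariance,
)


def one_factor_spec(n_ind=3, anchor=1.0):
    return SemSpecification(
        latents={"g": [(f"y{i+1}", anchor if i == 0 else None)
                       for i in range(n_ind)]},
        indicator_regressions=[], structural=[], exogenous=())


class TestModelImpliedCovariance:
    def test_unit_loadings_zero_residuals(self):
        spec = SemSpecification(
            latents={"g": [("y1", 1.0), ("y2", 1.0)]},
            indicator_regressions=[], structural=[], exogenous=())
        sigma = model_implied_covariance(
            spec, {"var(g)": 1.0, "var(y1)": 0.0, "var(y2)": 0.0})
        np.testing.assert_allclose(sigma.to_numpy(), np.ones((2, 2)))

    def test_zero_loadings_diagonal(self):
        spec = SemSpecification(
            latents={"g": [("y1", 0.0), ("y2", 0.0)]},
            indicator_regressions=[], structural=[], exogenous=())
        sigma = model_implied_covariance(
            spec, {"var(g)": 1.0, "var(y1)": 2.0, "var(y2)": 3.0})
        np.testing.assert_allclose(sigma.to_numpy(), np.diag([2.0, 3.0]))

    def test_always_symmetric_psd(self):
        rng = np.random.default_rng(0)
        spec = one_factor_spec(4)
        for _ in range(20):
            theta = {"g=~y2": rng.normal(), "g=~y3": rng.normal(),
                     "g=~y4": rng.normal(), "var(g)": rng.uniform(0.1, 2)}
            theta.update({f"var(y{i})": rng.uniform(0.05, 2) for i in range(1, 5)})
            sig = model_implied_covariance(spec, theta).to_numpy()
            np.testing.assert_allclose(sig, sig.T)
            assert np.linalg.eigvalsh(sig).min() > -1e-10

    def test_negative_residual_variance_rejected(self):
        spec = one_factor_spec(2)
        with pytest.raises(ValueError):
            model_implied_covariance(
                spec, {"g=~y2": 1.0, "var(g)": 1.0, "var(y1)": -0.5,
                       "var(y2)": 1.0})


class TestMlDiscrepancy:
    def test_zero_at_equality(self):
        assert ml_discrepancy(np.eye(2), np.eye(2)) == 0.0

    def test_hand_value_on_diagonal_fixture(self):
        f = ml_discrepancy(np.diag([2.0, 2.0]), np.eye(2))
        assert f == pytest.approx(2.0 - np.log(4.0), abs=1e-12)

    def test_strictly_positive_off_optimum(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=(3, 3))
            S = a @ a.T + 3 * np.eye(3)
            assert ml_discrepancy(S, np.eye(3)) > 0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ml_discrepancy(np.eye(2), np.eye(3))


class TestFitSem:
    def test_just_identified_closed_form(self):
        """psi = s12*s13/s23, lam2 = s23/s13, lam3 = s23/s12; F_ML = 0."""
        S = np.array([[2.0, 1.0, 0.8],
                      [1.0, 2.0, 0.9],
                      [0.8, 0.9, 2.0]])
        fit = fit_sem(one_factor_spec(3), S=S, n=500)
        psi = S[0, 1] * S[0, 2] / S[1, 2]
        lam2 = S[1, 2] / S[0, 2]
        lam3 = S[1, 2] / S[0, 1]
        assert fit.converged
        assert fit.estimate("var(g)") == pytest.approx(psi, abs=1e-6)
        assert fit.estimate("g=~y2") == pytest.approx(lam2, abs=1e-6)
        assert fit.estimate("g=~y3") == pytest.approx(lam3, abs=1e-6)
        for i in range(3):
            resid = S[i, i] - psi * [1, lam2, lam3][i] ** 2
            assert fit.estimate(f"var(y{i+1})") == pytest.approx(resid, abs=1e-6)
        assert fit.indices.fmin == pytest.approx(0.0, abs=1e-9)
        assert fit.indices.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.indices.df == 0

    def test_matches_brute_force_minimizer(self):
        """Independent oracle: naive Sigma = psi*ll' + diag(theta) minimized
        by Nelder-Mead agrees with the analytic-gradient fitter."""
        rng = np.random.default_rng(7)
        lam = np.array([1.0, 0.8, -0.6, 0.5])
        g = rng.standard_normal(3000)
        Y = np.outer(g, lam) + rng.standard_normal((3000, 4))
        S = np.cov(Y, rowvar=False, ddof=1)

        def fml(params):
            l2, l3, l4, psi, t1, t2, t3, t4 = params
            if psi <= 0 or min(t1, t2, t3, t4) <= 0:
                return 1e6
            ll = np.array([1.0, l2, l3, l4])
            sigma = psi * np.outer(ll, ll) + np.diag([t1, t2, t3, t4])
            return ml_discrepancy(S, sigma)

        res = optimize.minimize(
            fml, x0=[0.5, 0.5, 0.5, 0.5, 1, 1, 1, 1], method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        fit = fit_sem(one_factor_spec(4), S=S, n=3000)
        brute = dict(zip(
            ["g=~y2", "g=~y3", "g=~y4", "var(g)",
             "var(y1)", "var(y2)", "var(y3)", "var(y4)"], res.x))
        for name, val in brute.items():
            assert fit.estimate(name) == pytest.approx(val, abs=1e-3)
        assert fit.indices.fmin == pytest.approx(res.fun, abs=1e-8)

    def test_saturated_model_zero_chi2(self):
        """A just-identified model reproduces an admissible S exactly."""
        lam = np.array([1.0, 0.8, 1.3])
        S = 1.2 * np.outer(lam, lam) + np.diag([0.5, 0.9, 0.7])
        fit = fit_sem(one_factor_spec(3), S=S, n=200)
        np.testing.assert_allclose(
            fit.model.implied_cov(fit.theta), S, atol=1e-5)
        assert fit.indices.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_non_identified_rejected_by_sample_size(self):
        with pytest.raises(ValueError, match="too small"):
            fit_sem(one_factor_spec(3), S=np.eye(3) + 0.5, n=5)

    def test_structural_recovery_with_exogenous(self):
        rng = np.random.default_rng(11)
        n = 8000
        x = rng.standard_normal(n)
        g = 0.9 * x + rng.standard_normal(n)
        data = pd.DataFrame({
            "x": x,
            "y1": g + 0.6 * rng.standard_normal(n),
            "y2": 0.7 * g + 0.6 * rng.standard_normal(n),
            "y3": -0.5 * g + 0.6 * rng.standard_normal(n),
            "z": 0.25 * g + 0.1 * x + 0.5 * rng.standard_normal(n)})
        spec = SemSpecification(
            latents={"g": [("y1", 1.0), ("y2", None), ("y3", None)]},
            indicator_regressions=[],
            structural=[("g", ("x",)), ("z", ("x", "g"))],
            exogenous=("x",))
        fit = fit_sem(spec, data=data)
        assert fit.converged
        assert fit.estimate("g~x") == pytest.approx(0.9, abs=0.05)
        assert fit.estimate("z~g") == pytest.approx(0.25, abs=0.03)
        assert fit.estimate("g=~y3") == pytest.approx(-0.5, abs=0.03)
        # |t| > 1.96 <=> p < .05 within the normal approximation
        prow = fit.params.dropna(subset=["t"])
        assert ((prow["t"].abs() > 1.96) == (prow["p"] < 0.05)).all()


class TestFitIndices:
    def test_rmsea_zero_when_chi2_below_df(self):
        out = fit_indices(20.0, 25, 1001, np.eye(2), np.eye(2), 3, -10.0)
        assert out["rmsea"] == 0.0

    def test_rmsea_hand_value(self):
        out = fit_indices(50.0, 25, 1001, np.eye(2), np.eye(2), 3, -10.0)
        assert out["rmsea"] == pytest.approx(np.sqrt(25 / 25000.0), abs=1e-9)

    def test_srmr_zero_at_perfect_fit(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        out = fit_indices(0.0, 1, 100, S, S, 2, -5.0)
        assert out["srmr"] == 0.0

    def test_aic_definition(self):
        out = fit_indices(0.0, 1, 100, np.eye(2), np.eye(2), 7, -123.0)
        assert out["aic"] == pytest.approx(-2 * -123.0 + 2 * 7)

    def test_negative_df_rejected(self):
        with pytest.raises(ValueError):
            fit_indices(1.0, -1, 100, np.eye(2), np.eye(2), 9, 0.0)

    def test_indices_invariant_to_variable_reordering(self):
        rng = np.random.default_rng(19)
        lam = np.array([1.0, 0.8, -0.6, 0.5])
        g = rng.standard_normal(2000)
        Y = np.outer(g, lam) + rng.standard_normal((2000, 4))
        cols = ["y1", "y2", "y3", "y4"]
        df = pd.DataFrame(Y, columns=cols)
        spec_a = one_factor_spec(4)
        fit_a = fit_sem(spec_a, data=df)
        # same model, indicators listed in reverse (anchor now y4)
        spec_b = SemSpecification(
            latents={"g": [("y4", 1.0), ("y3", None), ("y2", None),
                           ("y1", None)]},
            indicator_regressions=[], structural=[], exogenous=())
        fit_b = fit_sem(spec_b, data=df)
        assert fit_a.indices.rmsea == pytest.approx(fit_b.indices.rmsea, abs=1e-6)
        assert fit_a.indices.srmr == pytest.approx(fit_b.indices.srmr, abs=1e-5)


class TestFactorScores:
    def test_scores_track_truth(self, migraine_fit):
        art = migraine_fit
        merged = art["table"].merge(
            art["truth"]["persons"][["person_id", "gender_true"]], on="person_id")
        r = np.corrcoef(art["scores"].raw, merged["gender_true"])[0, 1]
        assert r > 0.8

    def test_bartlett_close_to_regression(self, migraine_fit):
        art = migraine_fit
        bart = factor_scores(art["fit"], art["table"], method="bartlett")
        r = np.corrcoef(bart.raw, art["scores"].raw)[0, 1]
        assert r > 0.9

    def test_permutation_equivariance(self, migraine_fit):
        art = migraine_fit
        perm = np.random.default_rng(0).permutation(len(art["table"]))
        scrambled = art["table"].iloc[perm].reset_index(drop=True)
        sc = factor_scores(art["fit"], scrambled)
        np.testing.assert_allclose(sc.raw, art["scores"].raw[perm], atol=1e-10)

    def test_near_noiseless_limit_reproduces_latent(self):
        rng = np.random.default_rng(2)
        g = rng.standard_normal(500)
        eps = 0.01 * rng.standard_normal((500, 3))
        data = pd.DataFrame({"y1": g + eps[:, 0], "y2": 0.8 * g + eps[:, 1],
                             "y3": -0.5 * g + eps[:, 2]})
        fit = fit_sem(one_factor_spec(3), data=data)
        sc = factor_scores(fit, data)
        np.testing.assert_allclose(sc.raw, g - g.mean(), atol=0.05)


class TestRescaleGender:
    def test_midpoint_maps_to_half(self):
        """Group means -0.5 / +0.5: a raw score of 0 lands on 0.5."""
        from gendersem.sem import GenderScores
        raw = np.array([-0.6, -0.4, 0.4, 0.6])
        female = np.array([False, False, True, True])
        sc, _ = rescale_gender(GenderScores(raw=raw), female)
        a, b = sc.transform
        assert a * 0.0 + b == pytest.approx(0.5)

    def test_group_means_forced_to_unit_interval_ends(self, migraine_fit):
        art = migraine_fit
        female = art["table"]["sex_binary"].to_numpy() == 1.0
        sc, _ = rescale_gender(art["scores"], female)
        assert abs(sc.rescaled[female].mean() - 1.0) <= 1e-12
        assert abs(sc.rescaled[~female].mean()) <= 1e-12

    def test_equal_group_means_rejected(self):
        from gendersem.sem import GenderScores
        raw = np.array([1.0, 1.0, 1.0, 1.0])
        female = np.array([True, True, False, False])
        with pytest.raises(ValueError, match="scale"):
            rescale_gender(GenderScores(raw=raw), female)

    def test_fitted_outcome_contribution_invariant(self, migraine_fit):
        """beta_gender * score is unchanged by the affine rescaling."""
        art = migraine_fit
        female = art["table"]["sex_binary"].to_numpy() == 1.0
        sc, params = rescale_gender(art["scores"], female, art["fit"].params)
        b_raw = art["fit"].estimate("migraine_incident~gender")
        b_new = float(params.loc[params["name"] == "migraine_incident~gender",
                                 "estimate"].iloc[0])
        contrib_raw = b_raw * art["scores"].raw
        a, b = sc.transform
        contrib_new = b_new * (sc.rescaled - b)
        np.testing.assert_allclose(contrib_raw, contrib_new, atol=1e-12)

    def test_rescaling_is_an_affine_reparameterization(self, migraine_fit):
        """Undoing the scale transform restores the estimation-scale
        parameters exactly, so the model discrepancy is unchanged."""
        art = migraine_fit
        fit = art["fit"]
        female = art["table"]["sex_binary"].to_numpy() == 1.0
        sc, params = rescale_gender(art["scores"], female, fit.params)
        a, _b = sc.transform
        restored = np.empty_like(fit.theta)
        rescaled = dict(zip(params["name"], params["estimate"]))
        for k, nm in enumerate(fit.model.param_names):
            v = rescaled[nm]
            if nm.startswith("gender=~") or nm.endswith("~gender"):
                v *= a
            elif nm.startswith("gender~"):
                v /= a
            elif nm == "var(gender)":
                v /= a ** 2
            restored[k] = v
        np.testing.assert_allclose(restored, fit.theta, rtol=1e-10)
        _, logdet_S = np.linalg.slogdet(fit.sample_cov)
        f_orig, _ = fit.model.objective_and_grad(
            fit.theta, fit.sample_cov, logdet_S)
        f_back, _ = fit.model.objective_and_grad(
            restored, fit.sample_cov, logdet_S)
        assert f_back == pytest.approx(f_orig, abs=1e-10)


class TestWeightedCovariance:
    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        Sw, mean, n_eff = weighted_covariance(X, np.full(50, 2.0))
        np.testing.assert_allclose(Sw, np.cov(X, rowvar=False, ddof=1))
        np.testing.assert_allclose(mean, X.mean(axis=0))
        assert n_eff == pytest.approx(50)

    def test_zero_weight_rows_equivalent_to_dropping(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2))
        w = np.ones(40)
        w[:10] = 0.0
        Sw, mean, n_eff = weighted_covariance(X, w)
        Sd, md, nd = weighted_covariance(X[10:], np.ones(30))
        np.testing.assert_allclose(Sw, Sd)
        np.testing.assert_allclose(mean, md)
        assert n_eff == pytest.approx(nd)

    def test_hand_weighted_mean(self):
        X = np.array([[0.0], [4.0]])
        _, mean, _ = weighted_covariance(X, np.array([1.0, 3.0]))
        assert mean[0] == pytest.approx(3.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_covariance(np.ones((3, 2)), np.zeros(3))
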