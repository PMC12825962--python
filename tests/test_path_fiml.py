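import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from quadmed import (
    GenerativeConfig,
    LongitudinalDataset,
    PathModelSpec,
    add_centered_quadratic,
    em_mvn,
    fit_indices,
    fit_indices_from_stats,
    fit_path_model,
    generate,
    little_mcar_test,
)
from quadmed.path_fiml import _independence_loglik

from conftest import ols_coefs


def simple_frame(n=200, seed=0, miss=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = 0.4 * x + rng.normal(size=n)
    y = 1.0 + 0.5 * x - 0.3 * z + rng.normal(size=n)
    frame = pd.DataFrame({"x": x, "z": z, "y": y})
    if miss:
        m = rng.random(frame.shape) < miss
        frame = frame.mask(m)
    return frame


class TestSpec:
    def test_cyclic_rejected(self):
        spec = PathModelSpec.from_strings(["a ~ b", "b ~ a"])
        with pytest.raises(ValueError, match="cyclic"):
            spec.validate()

    def test_residual_cov_on_directed_path_rejected(self):
        spec = PathModelSpec.from_strings(["m ~ x", "y ~ m"], ["m ~~ y"])
        with pytest.raises(ValueError, match="directed path"):
            spec.validate()

    def test_variable_ordering_topological(self):
        spec = PathModelSpec.from_strings(["y ~ m + x", "m ~ x"])
        vars_ = spec.variables
        assert vars_.index("m") < vars_.index("y")

    def test_parse_errors(self):
        with pytest.raises(ValueError, match="parse"):
            PathModelSpec.from_strings(["y ~"])
        with pytest.raises(ValueError, match="parse"):
            PathModelSpec.from_strings(["y ~ x"], ["y ~ x"])


class TestFitCompleteData:
    def test_single_equation_matches_ols(self):
        frame = simple_frame(n=300, seed=1)
        spec = PathModelSpec.from_strings(["y ~ x + z"])
        fit = fit_path_model(LongitudinalDataset.from_frame(frame), spec)
        beta = ols_coefs(frame, "y", ["x", "z"])
        assert fit.get("y~1") == pytest.approx(beta[0], abs=1e-6)
        assert fit.get("y~x") == pytest.approx(beta[1], abs=1e-6)
        assert fit.get("y~z") == pytest.approx(beta[2], abs=1e-6)

    def test_ols_se_agreement(self):
        # FIML observed-information SEs converge to classical OLS SEs
        frame = simple_frame(n=2000, seed=2)
        spec = PathModelSpec.from_strings(["y ~ x + z"])
        fit = fit_path_model(LongitudinalDataset.from_frame(frame), spec)
        X = np.column_stack([np.ones(len(frame)), frame[["x", "z"]].to_numpy()])
        resid = frame["y"].to_numpy() - X @ ols_coefs(frame, "y", ["x", "z"])
        s2 = resid @ resid / len(frame)  # ML residual variance
        se_ols = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert fit.get_se("y~x") == pytest.approx(se_ols[1], rel=0.05)

    def test_saturated_loglik_matches_closed_form(self):
        frame = simple_frame(n=150, seed=3)
        # y ~ x + z with free exogenous covariances is saturated for 3 vars
        spec = PathModelSpec.from_strings(["y ~ x + z"])
        fit = fit_path_model(LongitudinalDataset.from_frame(frame), spec)
        X = frame.to_numpy()
        mu = X.mean(axis=0)
        Sig = np.cov(X, rowvar=False, ddof=0)
        ll = stats.multivariate_normal(mu, Sig).logpdf(X).sum()
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_fiml_equals_ols_when_likelihood_factorizes(self):
        # no cross-equation residual covariance -> per-equation ML = OLS
        cfg = GenerativeConfig.from_dict(
            {"n_cases": 400, "seed": 19, "missing_rate": 0.0}
        )
        data, _, _ = add_centered_quadratic(generate(cfg), "adversity_w1")
        spec = PathModelSpec.from_strings(
            [
                "ec_w2 ~ ec_w1 + adversity_w1_c + adversity_w1_c2 + sex + age + income",
                "ek_w2 ~ ek_w1 + adversity_w1_c + adversity_w1_c2 + sex + age + income",
            ]
        )
        fit = fit_path_model(data, spec, compute_se=False)
        for y, preds in spec.equations:
            beta = ols_coefs(data.values, y, preds)
            for p_, b in zip(preds, beta[1:]):
                assert fit.get(f"{y}~{p_}") == pytest.approx(b, abs=1e-6)

    def test_full_model_matches_sur_oracle(self, complete_dataset, cascade_spec):
        """With unequal regressor sets and free residual covariances the
        complete-data MLE is the iterated-FGLS (SUR) solution, not OLS."""
        fit = fit_path_model(complete_dataset, cascade_spec, compute_se=False,
                             gtol=1e-10)
        V = complete_dataset.values
        betas = _sur_ml(V, cascade_spec.equations[:2])
        for (y, preds), b in zip(cascade_spec.equations[:2], betas):
            for p_, bv in zip(preds, b[1:]):
                assert fit.get(f"{y}~{p_}") == pytest.approx(bv, abs=2e-4)


def _sur_ml(V, eqs, max_iter=300):
    """Iterated feasible GLS: the ML fixed point for a SUR tier."""
    n = len(V)
    ys = [V[y].to_numpy(float) for y, _ in eqs]
    Xs = [
        np.column_stack([np.ones(n)] + [V[p].to_numpy(float) for p in preds])
        for _, preds in eqs
    ]
    betas = [np.linalg.lstsq(X, y, rcond=None)[0] for X, y in zip(Xs, ys)]
    ks = [X.shape[1] for X in Xs]
    ofs = np.cumsum([0] + ks)
    for _ in range(max_iter):
        E = np.column_stack([y - X @ b for y, X, b in zip(ys, Xs, betas)])
        W = np.linalg.inv(E.T @ E / n)
        A = np.zeros((ofs[-1], ofs[-1]))
        rhs = np.zeros(ofs[-1])
        for i in range(len(eqs)):
            for j in range(len(eqs)):
                A[ofs[i]:ofs[i + 1], ofs[j]:ofs[j + 1]] = W[i, j] * (Xs[i].T @ Xs[j])
            rhs[ofs[i]:ofs[i + 1]] = sum(
                W[i, j] * (Xs[i].T @ ys[j]) for j in range(len(eqs))
            )
        sol = np.linalg.solve(A, rhs)
        new = [sol[ofs[i]:ofs[i + 1]] for i in range(len(eqs))]
        if max(np.max(np.abs(a - b)) for a, b in zip(new, betas)) < 1e-13:
            betas = new
            break
        betas = new
    return betas


class TestFitMissingData:
    def test_parameter_recovery_large_n(self):
        cfg = GenerativeConfig.from_dict({"n_cases": 2000, "seed": 31})
        data, _, _ = add_centered_quadratic(generate(cfg), "adversity_w1")
        from quadmed.pipeline import cascade_model_spec

        spec = cascade_model_spec()
        fit = fit_path_model(data, spec)
        assert fit.converged
        truths = {
            "ec_w2~adversity_w1_c2": -0.18,
            "ek_w2~adversity_w1_c2": -0.12,
            "ec_w2~ec_w1": 0.40,
            "ek_w2~ek_w1": 0.44,
            "ext_w3~ec_w2": -0.13,
            "int_w3~ek_w2": -0.14,
            "int_w3~int_w1": 0.15,
            "ext_w3~ext_w1": 0.24,
        }
        for name, truth in truths.items():
            z = abs(fit.get(name) - truth) / fit.get_se(name)
            assert z < 3.0, f"{name}: est {fit.get(name)}, truth {truth}, z {z}"

    def test_nested_model_loglik_monotone(self, paper_like_dataset):
        # same variable set; freeing the exogenous covariances must not
        # lower the maximized log-likelihood
        data, _, _ = paper_like_dataset
        eqs = ["ec_w2 ~ ec_w1 + adversity_w1_c + adversity_w1_c2"]
        small = PathModelSpec.from_strings(eqs, exogenous_covariances=False)
        large = PathModelSpec.from_strings(eqs, exogenous_covariances=True)
        ll_small = fit_path_model(data, small, compute_se=False).loglik
        ll_large = fit_path_model(data, large, compute_se=False).loglik
        assert ll_large >= ll_small - 1e-6

    def test_standardized_beta_affine_invariant(self, paper_like_dataset):
        data, _, _ = paper_like_dataset
        spec = PathModelSpec.from_strings(["ec_w2 ~ ec_w1 + adversity_w1_c"])
        base = fit_path_model(data, spec, compute_se=False)
        rescaled = data.values.copy()
        rescaled["ec_w1"] = rescaled["ec_w1"] * 12.5 + 3.0
        refit = fit_path_model(
            LongitudinalDataset.from_frame(rescaled), spec, compute_se=False
        )
        assert refit.standardized["ec_w2~ec_w1"] == pytest.approx(
            base.standardized["ec_w2~ec_w1"], abs=1e-6
        )

    def test_se_is_sqrt_of_est_cov_diagonal(self, fitted_cascade):
        fit = fitted_cascade
        diag = np.diag(fit.est_cov.to_numpy())
        assert (diag >= 0).all()
        np.testing.assert_allclose(
            fit.se.to_numpy(), np.sqrt(diag), rtol=1e-10, atol=1e-14
        )

    def test_est_cov_symmetric_psd(self, fitted_cascade):
        C = fitted_cascade.est_cov.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        w = np.linalg.eigvalsh(C)
        assert w.min() >= -1e-10

    def test_standardized_matches_sd_ratio(self, fitted_cascade):
        fit = fitted_cascade
        sds = np.sqrt(np.diag(fit.implied_cov.to_numpy()))
        sd = dict(zip(fit.implied_cov.columns, sds))
        name = "ec_w2~adversity_w1_c2"
        expected = fit.get(name) * sd["adversity_w1_c2"] / sd["ec_w2"]
        assert fit.standardized[name] == pytest.approx(expected, abs=1e-12)

    def test_listwise_standardization_switch(self, paper_like_dataset):
        data, _, _ = paper_like_dataset
        spec = PathModelSpec.from_strings(["ec_w2 ~ ec_w1 + adversity_w1_c"])
        a = fit_path_model(data, spec, compute_se=False, std_method="implied")
        b = fit_path_model(data, spec, compute_se=False, std_method="listwise")
        # same coefficients, different standardization basis
        assert a.get("ec_w2~ec_w1") == pytest.approx(b.get("ec_w2~ec_w1"), abs=1e-8)
        assert a.standardized["ec_w2~ec_w1"] != b.standardized["ec_w2~ec_w1"]

    def test_missing_variable_rejected(self, paper_like_dataset):
        data, _, _ = paper_like_dataset
        spec = PathModelSpec.from_strings(["ec_w2 ~ not_a_column"])
        with pytest.raises(ValueError, match="not_a_column"):
            fit_path_model(data, spec)


class TestEmMvn:
    def test_complete_data_equals_sample_moments(self):
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal([1, -1], [[2, 0.5], [0.5, 1]], size=400)
        mu, Sig, ll, conv = em_mvn(X)
        assert conv
        np.testing.assert_allclose(mu, X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(Sig, np.cov(X, rowvar=False, ddof=0), atol=1e-7)

    def test_em_matches_direct_optimization(self):
        # independent numerical maximization of the observed-data likelihood
        rng = np.random.default_rng(6)
        X = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=120)
        X[rng.random(X.shape) < 0.25] = np.nan
        X = X[~np.isnan(X).all(axis=1)]
        mu, Sig, ll, _ = em_mvn(X, tol=1e-13)

        def negll(t):
            m = t[:2]
            L = np.array([[np.exp(t[2]), 0], [t[3], np.exp(t[4])]])
            S = L @ L.T
            out = 0.0
            for row in X:
                o = ~np.isnan(row)
                sub = S[np.ix_(o, o)]
                out -= stats.multivariate_normal(m[o], sub).logpdf(row[o])
            return out

        res = optimize.minimize(negll, [0, 0, 0, 0.3, 0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 5000})
        assert ll == pytest.approx(-res.fun, abs=1e-4)


class TestFitIndices:
    def test_saturated_model_perfect_fit(self):
        frame = simple_frame(n=120, seed=7)
        spec = PathModelSpec.from_strings(["y ~ x + z"])
        data = LongitudinalDataset.from_frame(frame)
        fit = fit_path_model(data, spec)
        idx = fit_indices(fit, data, spec)
        assert idx.df == 0
        assert idx.chi2 == pytest.approx(0.0, abs=1e-4)
        assert idx.cfi == 1.0
        assert idx.rmsea == 0.0

    def test_truncation_behavior_printed_values(self):
        # chi2 below df truncates both indices
        idx = fit_indices_from_stats(7.52, 8, 500.0, 36, 238)
        assert idx.cfi == 1.0
        assert idx.rmsea == 0.0
        assert idx.p_value == pytest.approx(stats.chi2.sf(7.52, 8))

    def test_rmsea_formula(self):
        idx = fit_indices_from_stats(20.0, 10, 500.0, 36, 101)
        assert idx.rmsea == pytest.approx(np.sqrt(10.0 / (10 * 100)))

    def test_df_equals_moments_minus_params(self, fitted_cascade, paper_like_dataset,
                                            cascade_spec):
        data, _, _ = paper_like_dataset
        idx = fit_indices(fitted_cascade, data, cascade_spec)
        p = len(cascade_spec.variables)
        assert idx.df == p * (p + 3) // 2 - fitted_cascade.n_params
        assert idx.df == 8  # the canonical cascade model's constraint count

    def test_cfi_interior_value(self):
        idx = fit_indices_from_stats(30.0, 10, 110.0, 20, 200)
        assert idx.cfi == pytest.approx(1.0 - 20.0 / 90.0)

    def test_independence_loglik_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 2))
        ll, k = _independence_loglik(X)
        expect = sum(
            stats.norm(X[:, j].mean(), X[:, j].std()).logpdf(X[:, j]).sum()
            for j in range(2)
        )
        assert k == 4
        assert ll == pytest.approx(expect, abs=1e-8)


class TestLittleMcar:
    def test_no_missing_not_applicable(self):
        frame = simple_frame(n=50, seed=9)
        res = little_mcar_test(LongitudinalDataset.from_frame(frame))
        assert not res.applicable
        assert res.chi2 == 0.0 and res.df == 0

    def test_hand_computed_two_pattern_table(self):
        # 8 cases, 2 variables; pattern 1 = both observed, pattern 2 = x only
        frame = pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0, 12.0],
                "y": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0, np.nan, np.nan],
            }
        )
        res = little_mcar_test(frame)
        X = frame.to_numpy()
        mu, Sig, _, _ = em_mvn(X, tol=1e-13)
        # brute-force evaluation of the statistic
        d1 = X[:6].mean(axis=0) - mu
        c1 = 6 * d1 @ np.linalg.solve(Sig, d1)
        d2 = X[6:, 0].mean() - mu[0]
        c2 = 2 * d2**2 / Sig[0, 0]
        assert res.chi2 == pytest.approx(c1 + c2, abs=1e-6)
        assert res.df == (2 + 1) - 2
        assert res.n_patterns == 2

    def test_df_pattern_sum_invariant(self, paper_like_dataset):
        data, _, _ = paper_like_dataset
        cols = ["adversity_w1", "ec_w2", "ek_w2", "int_w3", "ext_w3"]
        res = little_mcar_test(data, variables=cols)
        obs = data.values[cols].notna()
        obs = obs[obs.any(axis=1)]
        expected_df = (
            obs.groupby(list(cols)).size().reset_index()
            .apply(lambda r: sum(r[c] for c in cols), axis=1).sum()
        )
        assert res.df == int(expected_df) - len(cols)

    def test_detects_mnar_mechanism(self):
        # deleting the largest y values is decidedly not MCAR
        rng = np.random.default_rng(10)
        x = rng.normal(size=400)
        y = 0.6 * x + rng.normal(size=400)
        frame = pd.DataFrame({"x": x, "y": y})
        frame.loc[frame["y"] > 0.5, "y"] = np.nan
        res = little_mcar_test(frame)
        assert res.p_value < 0.01
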