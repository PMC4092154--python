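import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from zicpue.errors import ValidationError
from zicpue.zigam import (
    ConstrainedZeroInflatedGAM,
    ModelSpec,
    PoissonGAM,
    ZeroInflatedGAM,
    fit_gam,
    fit_zigam,
    log_marginal_likelihood,
    predict_partial,
    summarize_fit,
)


def zip_loglik(params, y):
    """Observed-data ZIP log-likelihood, intercept-only (logit p, log mu)."""
    p = expit(params[0])
    mu = np.exp(params[1])
    zeros = y == 0
    ll = np.sum(np.log((1 - p) + p * np.exp(-mu)) * zeros)
    ll += np.sum((np.log(p) + y * np.log(mu) - mu - gammaln(y + 1)) * (~zeros))
    return ll


class TestPoissonGAM:
    def test_offset_algebra_intercept_only(self):
        # response equal to c * hooks in expectation: intercept ~ log c
        rng = np.random.default_rng(0)
        hooks = rng.integers(100, 500, 400).astype(float)
        c = 0.01
        y = rng.poisson(c * hooks)
        df = pd.DataFrame({"effort_hooks": hooks})
        fit = PoissonGAM().fit(df, y)
        assert fit.coef_[0] == pytest.approx(np.log(c), abs=0.05)

    def test_smooth_recovery_rmse(self, zip_frame):
        df, mu, _ = zip_frame(n=1000, seed=1, p_fun=lambda x: np.ones_like(x))
        fit = PoissonGAM(smooth_terms=[("x", 10)]).fit(df, df["y"])
        grid = np.linspace(0.5, 9.5, 60)
        eff = predict_partial(fit, "s(x)", grid)["effect"].to_numpy()
        truth = np.sin(grid) - np.mean(np.sin(df["x"]))
        rmse = np.sqrt(np.mean((eff - truth) ** 2))
        assert rmse < 0.15

    def test_row_permutation_invariance(self, zip_frame):
        df, *_ = zip_frame(n=300, seed=2, p_fun=lambda x: np.ones_like(x))
        fit1 = PoissonGAM(smooth_terms=[("x", 8)]).fit(df, df["y"])
        perm = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        fit2 = PoissonGAM(smooth_terms=[("x", 8)]).fit(perm, perm["y"])
        assert fit1.log_evidence_ == pytest.approx(fit2.log_evidence_, abs=1e-6)
        assert np.allclose(sorted(fit1.coef_), sorted(fit2.coef_), atol=1e-6)

    def test_all_zero_response_guarded(self):
        df = pd.DataFrame({"effort_hooks": np.full(50, 100.0)})
        with pytest.warns(RuntimeWarning, match="all-zero"):
            fit = PoissonGAM().fit(df, np.zeros(50))
        assert fit.coef_[0] <= -20


class TestZIGAM:
    def test_degenerate_mixture_matches_gam(self, zip_frame):
        # data simulated with p == 1: fitted p high, count smooth ~ GAM's
        df, *_ = zip_frame(n=600, seed=3, p_fun=lambda x: np.ones_like(x))
        zig = ZeroInflatedGAM(smooth_terms=[("x", 8)]).fit(df, df["y"])
        gam = PoissonGAM(smooth_terms=[("x", 8)]).fit(df, df["y"])
        assert np.all(zig.fitted_p_ > 0.95)
        grid = np.linspace(1, 9, 40)
        ez = predict_partial(zig, "s(x)", grid)
        eg = predict_partial(gam, "s(x)", grid)
        assert np.all(
            np.abs(ez["effect"] - eg["effect"]) <= 2 * (ez["se"] + eg["se"]) + 1e-6
        )

    def test_intercept_only_matches_brute_force_zip_mle(self):
        rng = np.random.default_rng(4)
        n = 2000
        p_true, mu_true = 0.6, 3.0
        y = np.where(rng.random(n) < p_true, rng.poisson(mu_true, n), 0)
        df = pd.DataFrame({"effort_hooks": np.ones(n)})
        zig = ZeroInflatedGAM(offset="effort_hooks").fit(df, y)
        # independent oracle: direct 2-parameter numeric MLE
        res = minimize(
            lambda th: -zip_loglik(th, y), x0=[0.0, 0.5], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10},
        )
        logit_p_hat = zig.zero_coef_[0]
        log_mu_hat = zig.coef_[0]
        assert logit_p_hat == pytest.approx(res.x[0], abs=0.01)
        assert log_mu_hat == pytest.approx(res.x[1], abs=0.01)
        # and the estimates sit near the generating values
        assert expit(logit_p_hat) == pytest.approx(p_true, abs=0.1)
        assert np.exp(log_mu_hat) == pytest.approx(mu_true, abs=0.1)

    def test_em_monotone_on_every_fixture(self, zip_frame):
        for seed in range(4):
            df, *_ = zip_frame(n=400, seed=seed)
            zig = ZeroInflatedGAM(smooth_terms=[("x", 8)]).fit(df, df["y"])
            assert np.all(np.diff(zig.em_loglik_path_) >= -1e-8)
            assert zig.n_em_iter_ <= 250

    def test_no_zeros_falls_back_to_gam(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(8.0, 200) + 1
        df = pd.DataFrame({"effort_hooks": np.full(200, 100.0)})
        zig = ZeroInflatedGAM().fit(df, y)
        assert zig.notes_
        assert np.all(zig.fitted_p_ > 0.999)

    def test_offset_shift_invariance(self, zip_frame):
        df, *_ = zip_frame(n=500, seed=6)
        c = 3.0
        df2 = df.assign(effort_hooks=df["effort_hooks"] * c)
        f1 = ZeroInflatedGAM(smooth_terms=[("x", 8)]).fit(df, df["y"])
        f2 = ZeroInflatedGAM(smooth_terms=[("x", 8)]).fit(df2, df2["y"])
        assert f2.coef_[0] == pytest.approx(f1.coef_[0] - np.log(c), abs=1e-3)
        assert np.allclose(f2.coef_[1:], f1.coef_[1:], atol=1e-3)

    def test_fractional_counts_rejected(self):
        df = pd.DataFrame({"effort_hooks": np.ones(10)})
        with pytest.raises(ValidationError):
            ZeroInflatedGAM().fit(df, np.linspace(0, 1, 10))

    def test_nesting_evidence_vs_gam_with_structural_zeros(self, zip_frame):
        # >= 30% structural zeros: the mixture's evidence beats (or nearly
        # matches) the plain GAM's
        for seed in range(3):
            df, *_ = zip_frame(n=500, seed=10 + seed,
                               p_fun=lambda x: np.full_like(x, 0.4))
            spec_g = ModelSpec("GAM", "y", smooth_terms=(("x", 8),),
                               offset="effort_hooks")
            spec_z = ModelSpec("ZIGAM", "y", smooth_terms=(("x", 8),),
                               offset="effort_hooks")
            zg = fit_gam(spec_g, df)
            zz = fit_zigam(spec_z, df)
            assert zz.log_evidence_ >= zg.log_evidence_ - 5.0

    def test_recovery_improves_with_n(self, zip_frame):
        # link-scale smooth RMSE at n=2000 below RMSE at n=200 (averaged)
        def rmse_at(n, seed):
            df, *_ = zip_frame(n=n, seed=seed,
                               p_fun=lambda x: np.full_like(x, 0.5))
            fit = ZeroInflatedGAM(smooth_terms=[("x", 8)]).fit(df, df["y"])
            grid = np.linspace(0.5, 9.5, 50)
            eff = predict_partial(fit, "s(x)", grid)["effect"].to_numpy()
            truth = np.sin(grid) - np.mean(np.sin(df["x"]))
            return np.sqrt(np.mean((eff - truth) ** 2))

        seeds = range(30, 40)
        small = np.mean([rmse_at(200, s) for s in seeds])
        large = np.mean([rmse_at(2000, s) for s in seeds])
        assert large < small


class TestCOZIGAM:
    def test_constraint_recovery(self):
        # data generated WITH the constraint true: (alpha, delta) recovered
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.uniform(0, 10, n)
        hooks = np.full(n, 400.0)
        lmu = np.log(hooks) - 5.2 + 1.2 * np.sin(x)
        alpha, delta = -2.0, 1.0
        p = expit(alpha + delta * lmu)
        y = np.where(rng.random(n) < p, rng.poisson(np.exp(lmu)), 0)
        df = pd.DataFrame({"x": x, "effort_hooks": hooks, "y": y})
        co = ConstrainedZeroInflatedGAM(smooth_terms=[("x", 10)]).fit(df, y)
        assert co.alpha_ == pytest.approx(alpha, abs=0.3)
        assert co.delta_ == pytest.approx(delta, abs=0.3)

    def test_delta_zero_matches_constant_p_zigam(self, zip_frame):
        df, *_ = zip_frame(n=600, seed=13)
        co = ConstrainedZeroInflatedGAM(
            smooth_terms=[("x", 8)], fix_delta=0.0
        ).fit(df, df["y"])
        zig = ZeroInflatedGAM(
            smooth_terms=[("x", 8)], zero_terms=((), ())
        ).fit(df, df["y"])
        assert co.alpha_ == pytest.approx(zig.zero_coef_[0], abs=1e-3)
        assert np.allclose(co.coef_, zig.coef_, atol=1e-3)


class TestSummaries:
    def test_null_model_dev_expl_zero(self):
        rng = np.random.default_rng(14)
        y = np.where(rng.random(300) < 0.4, rng.poisson(2.0, 300), 0)
        df = pd.DataFrame({"effort_hooks": np.full(300, 100.0)})
        zig = ZeroInflatedGAM().fit(df, y)
        assert zig.dev_expl_ == pytest.approx(0.0, abs=1e-9)

    def test_strong_signal_significant(self, zip_frame):
        df, *_ = zip_frame(n=800, seed=15, f=lambda x: 1.5 * np.sin(x),
                           p_fun=lambda x: np.full_like(x, 0.6))
        zig = ZeroInflatedGAM(smooth_terms=[("x", 8)]).fit(df, df["y"])
        summ = summarize_fit(zig)
        row = summ[summ["term"] == "s(x)"].iloc[0]
        assert row["p_value"] < 0.001
        assert 0 < row["edf"] <= 7
        assert summ.attrs["dev_expl"] > 0.1

    def test_log_marginal_likelihood_accessor(self, zip_frame):
        df, *_ = zip_frame(n=200, seed=16)
        zig = ZeroInflatedGAM(smooth_terms=[("x", 6)]).fit(df, df["y"])
        assert log_marginal_likelihood(zig) == zig.log_evidence_


class TestPartialEffects:
    def test_band_positive_width_and_coverage(self, zip_frame):
        grid = np.linspace(0.5, 9.5, 40)
        covered = []
        for seed in range(20):
            df, *_ = zip_frame(n=600, seed=100 + seed,
                               p_fun=lambda x: np.ones_like(x))
            fit = PoissonGAM(smooth_terms=[("x", 10)]).fit(df, df["y"])
            eff = predict_partial(fit, "s(x)", grid)
            assert np.all(eff["se"] > 0)
            truth = np.sin(grid) - np.mean(np.sin(df["x"]))
            covered.append(
                np.mean((eff["lo"] <= truth) & (truth <= eff["hi"]))
            )
        assert np.mean(covered) >= 0.85

    def test_null_covariate_band_contains_zero(self, zip_frame):
        grid = np.linspace(0.5, 9.5, 40)
        contain = []
        rng = np.random.default_rng(17)
        for seed in range(10):
            df, *_ = zip_frame(n=500, seed=200 + seed,
                               p_fun=lambda x: np.ones_like(x))
            df["noise"] = rng.uniform(0, 10, len(df))
            fit = PoissonGAM(smooth_terms=[("x", 8), ("noise", 8)]).fit(
                df, df["y"]
            )
            eff = predict_partial(fit, "s(noise)", grid)
            contain.append(np.mean((eff["lo"] <= 0) & (0 <= eff["hi"])))
        assert np.mean(contain) >= 0.90

    def test_unknown_term_raises(self, zip_frame):
        df, *_ = zip_frame(n=200, seed=18)
        fit = PoissonGAM(smooth_terms=[("x", 6)]).fit(df, df["y"])
        with pytest.raises(KeyError):
            predict_partial(fit, "s(zz)", np.linspace(0, 1, 5))


class TestSklearnContract:
    def test_get_set_params_roundtrip(self):
        est = ZeroInflatedGAM(smooth_terms=[("x", 8)], em_tol=1e-5)
        params = est.get_params()
        est2 = ZeroInflatedGAM(**params)
        assert est2.get_params() == params
        est2.set_params(em_tol=1e-7)
        assert est2.em_tol == 1e-7

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = clone(PoissonGAM(smooth_terms=[("x", 6)]))
        assert est.smooth_terms == [("x", 6)]
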