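import numpy as np
import pandas as pd
import pytest

from zicpue.errors import SelectionError
from zicpue.selection import (
    adjudicate_model_type,
    build_spt_specs,
    forward_stepwise_env,
    optimize_basis_dim,
    site_effect_tests,
)
from zicpue.simulate import (
    Scenario,
    SyntheticTruth,
    simulate_catches,
    simulate_environment,
)
from zicpue.zigam import ModelSpec, fit_zigam


def make_frame(n, seed, count_smooths, zero_intercept=-0.7, site_effects=None,
               baseline=-5.8, zero_smooths=None):
    """Survey-like frame with environment covariates and ZIP catches."""
    env = simulate_environment(Scenario(n_nearshore=n, n_cs=0, seed=seed))
    truth = SyntheticTruth(
        count_smooths=count_smooths,
        zero_smooths=zero_smooths or {},
        site_effects=site_effects or {"BV": 0.0, "PA": 0.0},
        baseline_log_rate=baseline,
        zero_intercept=zero_intercept,
    )
    env["count_sp"] = simulate_catches(env, {"sp": truth}, seed=seed)["sp"]
    return env


class TestOptimizeBasisDim:
    def test_singleton_grid(self):
        frame = make_frame(150, 0, {"temp": lambda t: 0.3 * (t - 27.5)})
        assert optimize_basis_dim(frame, "sp", "temp", k_grid=[6]) == 6

    def test_linear_truth_prefers_small_k(self):
        wins = 0
        for seed in range(3):
            frame = make_frame(
                300, seed, {"temp": lambda t: 0.45 * (t - 27.5)}
            )
            k = optimize_basis_dim(frame, "sp", "temp", k_grid=[4, 8, 12])
            wins += k == 4
        assert wins >= 2

    def test_wiggly_truth_needs_larger_k(self):
        chosen = []
        for seed in range(3):
            frame = make_frame(
                400, seed + 10,
                {"lunday": lambda d: 1.0 * np.sin(4.0 * np.pi * (d - 1) / 29.0)},
                zero_intercept=1.0,
            )
            chosen.append(
                optimize_basis_dim(frame, "sp", "lunday", k_grid=[4, 8, 12])
            )
        assert np.median(chosen) >= 8

    def test_empty_grid_errors(self):
        frame = make_frame(100, 1, {})
        with pytest.raises(SelectionError):
            optimize_basis_dim(frame, "sp", "temp", k_grid=[])


class TestAdjudication:
    def test_default_zero_inflated_scenario_chooses_zigam(self, survey):
        table, chosen = adjudicate_model_type(
            survey.cruises, "ginglymostoma cirratum", ["month", "lunday"]
        )
        assert chosen == "ZIGAM"
        key = ("ginglymostoma cirratum", "month", "ZIGAM")
        assert table[key] > table[("ginglymostoma cirratum", "month", "GAM")]

    def test_pure_poisson_scenario_gam_close_to_zigam(self):
        frame = make_frame(
            400, 2, {"temp": lambda t: 0.3 * (t - 27.5)}, zero_intercept=30.0
        )
        table, _ = adjudicate_model_type(frame, "sp", ["temp", "lunday"])
        close = 0
        for pred in ("temp", "lunday"):
            g = table[("sp", pred, "GAM")]
            z = table[("sp", pred, "ZIGAM")]
            close += g is not None and z is not None and abs(g - z) < 3.0
        assert close >= 1

    def test_failed_fit_recorded_not_fatal(self):
        frame = make_frame(120, 3, {})
        frame["binary"] = (frame.index % 2).astype(float)  # 2 distinct values
        table, chosen = adjudicate_model_type(frame, "sp", ["binary"])
        assert table[("sp", "binary", "ZIGAM")] is None
        assert chosen in ("GAM", "ZIGAM", "COZIGAM")


class TestSPTSpecs:
    def test_structures(self):
        spt1, spt2 = build_spt_specs(["BV", "PA", "CS"], response="count_sp")
        assert len(spt1.smooth_terms) == 2
        assert len(spt2.smooth_terms) == 1
        assert spt2.smooth_terms[0][0] == ("year", "month")
        assert spt1.factor_terms == (("site", "BV"),)

    def test_needs_two_sites(self):
        with pytest.raises(SelectionError):
            build_spt_specs(["BV"])

    def test_interaction_truth_favors_spt2(self):
        # seasonality whose phase drifts across years: only the shared
        # bivariate smooth can track it
        wins = 0
        for seed in range(3):
            env = simulate_environment(
                Scenario(n_nearshore=300, n_cs=30, seed=40 + seed)
            )
            phase = 2.0 * np.pi * (env["year"] - 2005) / 7.0
            f = 1.1 * np.sin(2.0 * np.pi * env["month"] / 12.0 + phase)
            rng = np.random.default_rng(seed)
            mu = np.exp(np.log(env["effort_hooks"]) - 5.8 + f)
            p = 0.55
            env["count_sp"] = np.where(
                rng.random(len(env)) < p, rng.poisson(mu), 0
            )
            spt1, spt2 = build_spt_specs(
                ["BV", "PA", "CS"], response="count_sp", k_year=4,
                k_month=6, k_2d=14,
            )
            f1 = fit_zigam(spt1, env)
            f2 = fit_zigam(spt2, env)
            wins += f2.log_evidence_ > f1.log_evidence_
        assert wins >= 2

    def test_additive_truth_fits_spt1_at_least_as_well(self):
        wins = 0
        for seed in range(3):
            env = simulate_environment(
                Scenario(n_nearshore=300, n_cs=30, seed=60 + seed)
            )
            f = (
                0.9 * np.sin(2.0 * np.pi * env["month"] / 12.0)
                - 0.12 * (env["year"] - 2008)
            )
            rng = np.random.default_rng(seed)
            mu = np.exp(np.log(env["effort_hooks"]) - 5.8 + f)
            env["count_sp"] = np.where(
                rng.random(len(env)) < 0.55, rng.poisson(mu), 0
            )
            spt1, spt2 = build_spt_specs(
                ["BV", "PA", "CS"], response="count_sp", k_year=4,
                k_month=6, k_2d=14,
            )
            f1 = fit_zigam(spt1, env)
            f2 = fit_zigam(spt2, env)
            wins += f1.dev_expl_ >= f2.dev_expl_
        assert wins >= 2


class TestForwardStepwise:
    def test_temp_only_truth_selected(self):
        hits = 0
        for seed in range(3):
            frame = make_frame(
                350, 70 + seed, {"temp": lambda t: 0.8 * np.tanh(t - 27.5)},
                zero_intercept=0.3,
            )
            trace = forward_stepwise_env(
                frame, "sp", ["temp", "salin", "lunday"], k=6
            )
            covs = {t[0][0] for t in trace.final_spec.smooth_terms}
            hits += covs == {"temp"}
        assert hits >= 2

    def test_exclusion_constraint_respected(self):
        # temp and visib are rank-correlated and both informative; with the
        # pair excluded the final model contains exactly one of them
        frame = make_frame(
            350, 80, {"temp": lambda t: 0.9 * (t - 27.5) / 1.2},
            zero_intercept=0.3,
        )
        trace = forward_stepwise_env(
            frame, "sp", ["temp", "visib"], exclusions=[("temp", "visib")],
            k=6,
        )
        covs = {t[0][0] for t in trace.final_spec.smooth_terms}
        assert len(covs & {"temp", "visib"}) <= 1
        if covs:
            assert covs <= {"temp", "visib"}

    def test_noise_candidates_rejected(self):
        empties = 0
        for seed in range(3):
            frame = make_frame(300, 90 + seed, {}, zero_intercept=0.3)
            trace = forward_stepwise_env(
                frame, "sp", ["salin", "lunday"], k=6
            )
            empties += len(trace.final_spec.smooth_terms) == 0
        assert empties >= 2

    def test_trace_increasing_and_deterministic(self):
        frame = make_frame(
            300, 95, {"temp": lambda t: 0.7 * np.tanh(t - 27.5)},
            zero_intercept=0.3,
        )
        t1 = forward_stepwise_env(frame, "sp", ["temp", "salin"], k=6)
        accepted = t1.accepted_logE()
        assert all(b > a for a, b in zip(accepted, accepted[1:]))
        t2 = forward_stepwise_env(frame, "sp", ["temp", "salin"], k=6)
        assert [s["logE"] for s in t1.steps] == [s["logE"] for s in t2.steps]


class TestSiteEffects:
    def _site_frame(self, seed, pa_effect):
        env = simulate_environment(Scenario(n_nearshore=518, n_cs=0, seed=seed))
        truth = SyntheticTruth(
            count_smooths={},
            site_effects={"BV": 0.0, "PA": pa_effect},
            baseline_log_rate=-5.6,
            zero_intercept=0.4,
        )
        env["count_sp"] = simulate_catches(env, {"sp": truth}, seed=seed)["sp"]
        return env

    def test_negative_site_effect_detected(self):
        frame = self._site_frame(5, -1.0)
        fit = fit_zigam(
            ModelSpec("ZIGAM", "count_sp", factor_terms=(("site", "BV"),)),
            frame,
        )
        res = site_effect_tests(fit)
        row = res[res["level"] == "PA"].iloc[0]
        assert row["z"] < -2.0
        assert "BV" not in set(res["level"])

    def test_null_site_effect_not_detected(self):
        frame = self._site_frame(6, 0.0)
        fit = fit_zigam(
            ModelSpec("ZIGAM", "count_sp", factor_terms=(("site", "BV"),)),
            frame,
        )
        row = site_effect_tests(fit).iloc[0]
        assert abs(row["z"]) < 2.0

    def test_missing_factor_raises(self, survey):
        fit = fit_zigam(
            ModelSpec("ZIGAM", "count_ginglymostoma cirratum"), survey.cruises
        )
        with pytest.raises(KeyError):
            site_effect_tests(fit)
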