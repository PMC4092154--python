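"""End-to-end pipeline binding the analysis stages.

read/filter/aggregate (or simulate) -> correlation screen -> model-class
adjudication -> SPT1/SPT2 spatiotemporal fits -> forward stepwise ENV
models -> assemblage statistics.  Every stage writes a delimited or
structured-text report into the run directory; a machine-readable run log
records the configuration and seed so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from zicpue import __version__
from zicpue.assemblage import (
    kruskal_wallis,
    kw_posthoc,
    length_ttest,
    sex_by_period_test,
    sex_ratio_gof,
)
from zicpue.errors import ConfigurationError, UndefinedTestError, ZicpueError
from zicpue.io import (
    ENV_COVARIATES,
    aggregate_by_cruise,
    apply_standardization_filters,
    cruises_to_frame,
    read_capture_table,
    read_set_table,
)
from zicpue.screening import screen_covariates, screen_report
from zicpue.selection import (
    adjudicate_model_type,
    build_spt_specs,
    forward_stepwise_env,
    site_effect_tests,
)
from zicpue.simulate import Scenario, default_scenario
from zicpue.zigam import fit_cozigam, fit_gam, fit_zigam, summarize_fit

_FITTERS = {"GAM": fit_gam, "ZIGAM": fit_zigam, "COZIGAM": fit_cozigam}

logger = logging.getLogger("zicpue")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str
    seed: int | None = None
    # either a synthetic scenario ...
    scenario: dict | None = None
    # ... or input tables
    set_table: str | None = None
    capture_table: str | None = None
    species: list[str] = field(default_factory=list)
    adjudication_predictors: list[str] = field(default_factory=lambda: ["month", "temp"])
    env_candidates: list[str] = field(
        default_factory=lambda: ["temp", "visib", "tidamp", "pluvio"]
    )
    k: int = 8
    k_year: int = 5
    k_month: int = 8
    k_2d: int = 20
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self):
        if not self.species:
            raise ConfigurationError("config lists no species")
        if self.scenario is None and self.set_table is None:
            raise ConfigurationError("config needs a scenario or a set_table")
        if self.scenario is not None and self.seed is None:
            raise ConfigurationError("a seed is required for synthetic scenarios")


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes: cruise_table.csv, screening.csv, adjudication.csv,
    spt_comparison.csv, env_trace.csv, assemblage.json, run_log.json.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- input stage -----------------------------------------------------
    _stage("input")
    if config.scenario is not None:
        scen_kwargs = dict(config.scenario)
        if scen_kwargs:
            from zicpue.simulate import (
                POSITIVE_CATCH_RATES,
                calibrate_baseline,
                default_truth,
                simulate_catches,
                simulate_environment,
                simulate_individuals,
            )

            scenario = Scenario(seed=config.seed, truth=default_truth(), **scen_kwargs)
            env = simulate_environment(scenario)
            truth = {
                sp: calibrate_baseline(env, tr, POSITIVE_CATCH_RATES[sp])
                for sp, tr in scenario.truth.items()
            }
            counts = simulate_catches(env, truth, seed=config.seed)
            cruises = env.copy()
            cap_rows = []
            for j, sp in enumerate(truth):
                cruises[f"count_{sp}"] = counts[sp]
                n_sp = int(counts[sp].sum())
                for r in simulate_individuals(
                    sp, n_sp, truth[sp], seed=(config.seed * 97 + j) % (2**31)
                ):
                    cap_rows.append(
                        {"species": r.species, "sex": r.sex, "tl_cm": r.tl_cm,
                         "date": r.date, "site": r.site}
                    )
            captures = pd.DataFrame(
                cap_rows, columns=["species", "sex", "tl_cm", "date", "site"]
            )
        else:
            survey = default_scenario(config.seed)
            cruises = survey.cruises
            captures = survey.captures
    else:
        sets = read_set_table(config.set_table)
        sets = apply_standardization_filters(sets)
        cruises = cruises_to_frame(aggregate_by_cruise(sets))
        captures = (
            pd.DataFrame(
                [
                    {"species": r.species, "sex": r.sex, "tl_cm": r.tl_cm,
                     "date": r.date, "site": r.site}
                    for r in read_capture_table(config.capture_table)
                ]
            )
            if config.capture_table
            else pd.DataFrame(columns=["species", "sex", "tl_cm", "date", "site"])
        )
    cruises.to_csv(outdir / "cruise_table.csv", index=False)

    # ---- correlation screen ----------------------------------------------
    _stage("screen")
    covs = [c for c in ENV_COVARIATES if c in cruises.columns]
    results, exclusions = screen_covariates(cruises, covs)
    screen_report(results).to_csv(outdir / "screening.csv", index=False)

    # ---- model-class adjudication ------------------------------------------
    _stage("adjudicate")
    table, chosen = adjudicate_model_type(
        cruises, config.species, config.adjudication_predictors, k=config.k
    )
    adj_rows = [
        {"species": sp, "predictor": pred, "model_type": m, "logE": v}
        for (sp, pred, m), v in table.items()
    ]
    adj = pd.DataFrame(adj_rows)
    adj.attrs["chosen"] = chosen
    adj.to_csv(outdir / "adjudication.csv", index=False)

    # ---- spatiotemporal models ---------------------------------------------
    _stage("spt")
    fitters = _FITTERS
    spt_rows = []
    for sp in config.species:
        response = f"count_{sp}" if f"count_{sp}" in cruises.columns else sp
        spt1, spt2 = build_spt_specs(
            sorted(cruises["site"].unique()), response=response,
            model_type=chosen, k_year=config.k_year, k_month=config.k_month,
            k_2d=config.k_2d,
        )
        for label, spec in (("SPT1", spt1), ("SPT2", spt2)):
            try:
                fit = fitters[chosen](spec, cruises)
            except ZicpueError as exc:
                spt_rows.append(
                    {"species": sp, "model": label, "term": "FAILED",
                     "note": str(exc)}
                )
                continue
            summ = summarize_fit(fit)
            for _, row in summ.iterrows():
                spt_rows.append(
                    {"species": sp, "model": label, "term": row["term"],
                     "edf": row["edf"], "ref_df": row["ref_df"],
                     "chi_sq": row["chi_sq"], "p_value": row["p_value"],
                     "r2_adj": row["r2_adj"], "dev_expl": row["dev_expl"],
                     "logE": fit.log_evidence_}
                )
            for _, row in site_effect_tests(fit).iterrows():
                spt_rows.append(
                    {"species": sp, "model": label,
                     "term": f"site[{row['level']}]",
                     "chi_sq": row["z"] ** 2, "p_value": row["p_value"],
                     "z": row["z"], "logE": fit.log_evidence_}
                )
    pd.DataFrame(spt_rows).to_csv(outdir / "spt_comparison.csv", index=False)

    # ---- ENV stepwise -------------------------------------------------------
    _stage("env")
    env_rows = []
    for sp in config.species:
        trace = forward_stepwise_env(
            cruises, sp, config.env_candidates, exclusions,
            model_type=chosen, k=config.k,
        )
        for step in trace.steps:
            env_rows.append(
                {"species": sp,
                 "candidate": step["candidate"] or "(base)",
                 "logE": step["logE"],
                 "accepted": step["accepted"]}
            )
        final_terms = ",".join(
            t[0][0] for t in (trace.final_spec.smooth_terms or ())
        )
        env_rows.append(
            {"species": sp, "candidate": f"FINAL[{final_terms}]",
             "logE": trace.final_fit.log_evidence_, "accepted": True}
        )
    pd.DataFrame(env_rows).to_csv(outdir / "env_trace.csv", index=False)

    # ---- assemblage statistics ----------------------------------------------
    _stage("assemblage")
    assemblage = {}
    for sp in sorted(captures["species"].unique()) if len(captures) else []:
        sub = captures[captures["species"] == sp]
        males = int((sub["sex"] == "M").sum())
        females = int((sub["sex"] == "F").sum())
        entry = {"n": int(len(sub)), "males": males, "females": females}
        try:
            gof = sex_ratio_gof(males, females)
            entry["sex_ratio_gof"] = {"chi_sq": gof.statistic, "df": gof.df,
                                      "p": gof.p}
        except UndefinedTestError:
            pass
        lt = sub.assign(q=pd.to_datetime(sub["date"]).dt.quarter)
        try:
            tt = length_ttest(
                lt.loc[lt["sex"] == "M", "tl_cm"], lt.loc[lt["sex"] == "F", "tl_cm"]
            )
            entry["length_ttest_mf"] = {"t": tt.statistic, "df": tt.df, "p": tt.p}
        except (UndefinedTestError, ZicpueError):
            pass
        groups = [g["tl_cm"].to_numpy() for _, g in lt.groupby("q")]
        labels = sorted(lt["q"].unique())
        if len(groups) >= 2:
            kw = kruskal_wallis(groups)
            entry["kw_quarters"] = {"H": kw.statistic, "df": kw.df, "p": kw.p}
            ph = kw_posthoc(groups, alpha=config.alpha, labels=labels)
            entry["kw_posthoc"] = [
                {"quarters": [int(a), int(b)], "diff_obs": d, "diff_crit": c,
                 "significant": s}
                for a, b, d, c, s in ph.pairs
            ]
        tab = pd.crosstab(lt["sex"], lt["q"])
        if tab.shape == (2, tab.shape[1]) and tab.shape[1] >= 2:
            try:
                sbq = sex_by_period_test(tab.to_numpy())
                entry["sex_by_quarter"] = {"chi_sq": sbq.statistic, "df": sbq.df,
                                           "p": sbq.p}
            except UndefinedTestError:
                pass
        assemblage[sp] = entry
    with open(outdir / "assemblage.json", "w") as fh:
        json.dump(assemblage, fh, indent=2, sort_keys=True)

    # ---- run log -------------------------------------------------------------
    log = {
        "package": "zicpue",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {
            k: v
            for k, v in vars(config).items()
            if not k.startswith("_") and k != "outdir"
        },
        "chosen_model_type": chosen,
        "excluded_pairs": [list(p) for p in exclusions],
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return outdir
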