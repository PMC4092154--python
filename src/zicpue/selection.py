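"""Model-selection workflow driven by the Laplace evidence (logE).

Four stages mirror the survey analysis protocol:

1. per-predictor optimization of the spline basis dimension k, comparing
   univariate zero-inflated fits by logE;
2. adjudication of the model class — plain Poisson GAM vs zero-inflated
   GAM vs constrained zero-inflated GAM — from univariate fits of every
   predictor (failures recorded, never fatal);
3. the spatiotemporal structures: SPT1 (site factor + independent year
   and month smooths) vs SPT2 (site factor + one shared bivariate
   year-month smooth);
4. forward stepwise construction of the environmental (ENV) model under
   the correlation-screen exclusion constraints, always retaining the
   site factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from zicpue.errors import SelectionError, ZicpueError
from zicpue.zigam import (
    ConstrainedZeroInflatedGAM,
    FittedModel,
    ModelSpec,
    fit_cozigam,
    fit_gam,
    fit_zigam,
)

__all__ = [
    "SelectionTrace",
    "optimize_basis_dim",
    "adjudicate_model_type",
    "build_spt_specs",
    "forward_stepwise_env",
    "site_effect_tests",
]

DEFAULT_K_GRID = (4, 6, 8, 10, 12)
STEPWISE_K = 8


@dataclass
class SelectionTrace:
    """Record of a stepwise search: every evaluation plus the final spec."""

    steps: list[dict] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: FittedModel | None = None
    adjudication_table: dict = field(default_factory=dict)

    def accepted_logE(self) -> list[float]:
        return [s["logE"] for s in self.steps if s["accepted"]]


def _resolve_response(data: pd.DataFrame, species: str) -> str:
    for cand in (f"count_{species}", species):
        if cand in data.columns:
            return cand
    raise SelectionError(f"no count column for species {species!r}")


def _univariate_spec(model_type, response, predictor, k) -> ModelSpec:
    return ModelSpec(
        model_type=model_type,
        response=response,
        smooth_terms=((predictor, k),),
    )


_FITTERS = {"GAM": fit_gam, "ZIGAM": fit_zigam, "COZIGAM": fit_cozigam}


def optimize_basis_dim(
    data: pd.DataFrame,
    species: str,
    predictor: str,
    k_grid=DEFAULT_K_GRID,
    model_type: str = "ZIGAM",
) -> int:
    """Choose the basis dimension maximizing univariate logE.

    Ties (within 1e-6) break toward the smaller k for parsimony.  Raises
    :class:`SelectionError` if every candidate fit fails.
    """
    if not k_grid:
        raise SelectionError("empty k grid")
    response = _resolve_response(data, species)
    best_k, best_le = None, -np.inf
    failures = []
    for k in sorted(k_grid):
        if k < 3:
            raise SelectionError(f"basis dimension {k} < 3")
        try:
            fit = _FITTERS[model_type](
                _univariate_spec(model_type, response, predictor, k), data
            )
            le = fit.log_evidence_
        except ZicpueError as exc:
            failures.append((k, str(exc)))
            continue
        if le > best_le + 1e-6:
            best_k, best_le = k, le
    if best_k is None:
        raise SelectionError(
            f"all basis-dimension fits failed for {predictor!r}: {failures}"
        )
    return best_k


def adjudicate_model_type(
    data: pd.DataFrame,
    species,
    predictors,
    k: int = STEPWISE_K,
) -> tuple[dict, str]:
    """Fit GAM / ZIGAM / COZIGAM univariately per predictor and vote.

    Returns the adjudication table mapping (species, predictor,
    model_type) to logE (or None for a failed fit) and the chosen type —
    the one with the highest logE for the most predictors, ties resolved
    toward ZIGAM.
    """
    species_list = [species] if isinstance(species, str) else list(species)
    table = {}
    votes = {"GAM": 0, "ZIGAM": 0, "COZIGAM": 0}
    for sp in species_list:
        response = _resolve_response(data, sp)
        for pred in predictors:
            row = {}
            for mtype, fitter in _FITTERS.items():
                kk = min(k, data[pred].nunique())
                try:
                    fit = fitter(
                        _univariate_spec(mtype, response, pred, max(kk, 3)), data
                    )
                    row[mtype] = float(fit.log_evidence_)
                except ZicpueError:
                    row[mtype] = None
                table[(sp, pred, mtype)] = row[mtype]
            valid = {m: v for m, v in row.items() if v is not None}
            if valid:
                votes[max(valid, key=valid.get)] += 1
    best = max(votes.values())
    winners = [m for m, v in votes.items() if v == best]
    chosen = "ZIGAM" if "ZIGAM" in winners else winners[0]
    return table, chosen


def build_spt_specs(
    sites,
    response: str = "count",
    model_type: str = "ZIGAM",
    k_year: int = 5,
    k_month: int = 8,
    k_2d: int = 20,
    offset: str = "effort_hooks",
) -> tuple[ModelSpec, ModelSpec]:
    """Spatiotemporal model pair for a given set of site levels.

    SPT1: site factor + s(year) + s(month); SPT2: site factor +
    s(year, month) as one isotropic bivariate smooth.  Reference level BV.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise SelectionError("need at least 2 site levels")
    ref = "BV" if "BV" in sites else sorted(sites)[0]
    spt1 = ModelSpec(
        model_type=model_type,
        response=response,
        smooth_terms=(("year", k_year), ("month", k_month)),
        factor_terms=(("site", ref),),
        offset=offset,
    )
    spt2 = ModelSpec(
        model_type=model_type,
        response=response,
        smooth_terms=((("year", "month"), k_2d),),
        factor_terms=(("site", ref),),
        offset=offset,
    )
    return spt1, spt2


def forward_stepwise_env(
    data: pd.DataFrame,
    species: str,
    candidates,
    exclusions=(),
    site_factor: bool = True,
    model_type: str = "ZIGAM",
    k: int = STEPWISE_K,
) -> SelectionTrace:
    """Forward stepwise ENV-model construction maximizing logE.

    Starts from the site factor (when requested) plus offset; at each step
    adds the candidate smooth with the largest logE among those not
    excluded against any already-included covariate; stops at the first
    step with no improvement.  The trace records every evaluation.
    """
    response = _resolve_response(data, species)
    excl = {frozenset(p) for p in exclusions}
    trace = SelectionTrace()
    base = ModelSpec(
        model_type=model_type,
        response=response,
        factor_terms=(("site", None),) if site_factor else (),
    )
    fitter = _FITTERS[model_type]
    current_fit = fitter(base, data)
    current_le = current_fit.log_evidence_
    trace.steps.append(
        {"spec": base, "candidate": None, "logE": float(current_le), "accepted": True}
    )
    included: list[str] = []
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            if any(frozenset((cand, inc)) in excl for inc in included):
                continue
            kk = max(3, min(k, data[cand].nunique()))
            spec = base.with_smooth(cand, kk)
            try:
                fit = fitter(spec, data)
                le = float(fit.log_evidence_)
            except ZicpueError:
                trace.steps.append(
                    {"spec": spec, "candidate": cand, "logE": None, "accepted": False}
                )
                continue
            trace.steps.append(
                {"spec": spec, "candidate": cand, "logE": le, "accepted": False}
            )
            if le > current_le + 1e-9 and (best is None or le > best[1]):
                best = (cand, le, spec, fit)
        if best is None:
            break
        cand, le, spec, fit = best
        for s in trace.steps:
            if s["candidate"] == cand and s["logE"] == le:
                s["accepted"] = True
        base, current_le, current_fit = spec, le, fit
        included.append(cand)
        remaining.remove(cand)
    trace.final_spec = base
    trace.final_fit = current_fit
    return trace


def site_effect_tests(fit: FittedModel, factor: str = "site") -> pd.DataFrame:
    """Wald Z tests of each non-reference site level against the reference."""
    term = None
    for t in fit.design_.terms:
        if t.kind == "factor" and t.name == factor:
            term = t
            break
    if term is None:
        raise KeyError(f"fitted model has no factor term {factor!r}")
    beta = fit.coef_[term.cols]
    se = np.sqrt(np.diag(fit.posterior_cov_)[term.cols])
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "level": term.levels[1:],
            "reference": term.levels[0],
            "coef": beta,
            "se": se,
            "z": z,
            "p_value": p,
        }
    )
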