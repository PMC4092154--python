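"""Poisson GAM, zero-inflated GAM (EM) and constrained zero-inflated GAM.

Catch counts per cruise are modeled as a probabilistic mixture of a
degenerate zero state and a regular Poisson state:

    y_i = 0                   with probability 1 - p_i
    y_i ~ Poisson(mu_i)       with probability p_i

    log mu_i    = log(effort_i) + beta' x_i      (count component)
    logit p_i   = gamma' w_i                     (zero component, ZIGAM)
    logit p_i   = alpha + delta * log mu_i       (COZIGAM constraint)

``p_i`` is the probability of the REGULAR (non-zero-inflated) state.  All
smooths are low-rank thin-plate regression splines; the log of fishing
effort enters the count component as an offset so that the fitted mean is
a standardized catch rate.  Because the state of a zero observation is
unobserved, the mixture is fitted by EM: the E-step computes the
responsibility of the regular state for each zero, and the M-step is a
responsibility-weighted Poisson fit plus a binomial fit to the fractional
responsibilities.  Smoothing parameters are chosen by maximizing the same
Laplace-approximated log marginal likelihood (logE) that is used for model
comparison, so selection and adjudication live on a single scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator

from zicpue.errors import ValidationError
from zicpue.glm import (
    ETA_CLIP,
    ComponentFit,
    Penalty,
    component_log_evidence,
    fit_penalized_glm,
)
from zicpue.splines import SmoothBasis, build_tprs_basis, build_tprs_basis_2d

__all__ = [
    "ModelSpec",
    "FittedModel",
    "PoissonGAM",
    "ZeroInflatedGAM",
    "ConstrainedZeroInflatedGAM",
    "fit_gam",
    "fit_zigam",
    "fit_cozigam",
    "log_marginal_likelihood",
    "summarize_fit",
    "predict_partial",
]

DEFAULT_K_1D = 10
DEFAULT_K_2D = 25
MAX_EM_ITER = 250
# coordinate-descent grid for log10(lambda) during evidence maximization
LAMBDA_GRID = tuple(10.0 ** np.array([-2.0, -0.5, 1.0, 2.5, 4.0, 5.5]))


# ---------------------------------------------------------------------------
# model specification


def _normalize_smooth_terms(smooth_terms) -> tuple:
    out = []
    for t in smooth_terms or ():
        if isinstance(t, str):
            out.append(((t,), None))
            continue
        cov, k = t
        if isinstance(cov, str):
            cov = (cov,)
        out.append((tuple(cov), None if k is None else int(k)))
    covs = [c for c, _ in out]
    if len(set(covs)) != len(covs):
        raise ValidationError("a covariate appears in smooth_terms twice")
    return tuple(out)


def _normalize_factor_terms(factor_terms) -> tuple:
    out = []
    for t in factor_terms or ():
        if isinstance(t, str):
            out.append((t, None))
        else:
            name, ref = t
            out.append((name, ref))
    return tuple(out)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model structure for one species' abundance model."""

    model_type: str  # "GAM" | "ZIGAM" | "COZIGAM"
    response: str
    smooth_terms: tuple = ()
    factor_terms: tuple = ()
    offset: str | None = "effort_hooks"
    zero_terms: object = "mirror"  # ZIGAM only; COZIGAM derives it

    def __post_init__(self):
        if self.model_type not in ("GAM", "ZIGAM", "COZIGAM"):
            raise ValidationError(f"unknown model type {self.model_type!r}")
        object.__setattr__(
            self, "smooth_terms", _normalize_smooth_terms(self.smooth_terms)
        )
        object.__setattr__(
            self, "factor_terms", _normalize_factor_terms(self.factor_terms)
        )

    def with_smooth(self, covariate, k=None) -> "ModelSpec":
        terms = self.smooth_terms + _normalize_smooth_terms([(covariate, k)])
        return replace(self, smooth_terms=terms)


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class TermInfo:
    name: str
    kind: str  # "intercept" | "factor" | "smooth"
    cols: np.ndarray
    covariates: tuple[str, ...]
    basis: SmoothBasis | None = None
    levels: list | None = None  # factor levels, reference first
    penalty_index: int | None = None


class _Design:
    """Assembled model matrix builder for one linear predictor."""

    def __init__(self, smooth_terms, factor_terms):
        self.smooth_terms = _normalize_smooth_terms(smooth_terms)
        self.factor_terms = _normalize_factor_terms(factor_terms)
        self.terms: list[TermInfo] = []
        self.penalties: list[Penalty] = []
        self.n_cols = 0

    def fit(self, data: pd.DataFrame) -> "_Design":
        self.terms = []
        self.penalties = []
        col = 0
        self.terms.append(
            TermInfo("intercept", "intercept", np.array([0]), ())
        )
        col = 1
        for name, ref in self.factor_terms:
            values = data[name].astype(str)
            levels = sorted(values.unique())
            if ref is None:
                ref = "BV" if "BV" in levels else levels[0]
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} absent from {name!r}")
            levels = [ref] + [lv for lv in levels if lv != ref]
            cols = np.arange(col, col + len(levels) - 1)
            self.terms.append(TermInfo(name, "factor", cols, (name,), levels=levels))
            col += len(levels) - 1
        for covs, k in self.smooth_terms:
            if len(covs) == 1:
                kk = DEFAULT_K_1D if k is None else k
                basis = build_tprs_basis(data[covs[0]].to_numpy(float), kk, covs[0])
            else:
                kk = DEFAULT_K_2D if k is None else k
                basis = build_tprs_basis_2d(
                    data[covs[0]].to_numpy(float),
                    data[covs[1]].to_numpy(float),
                    kk,
                    names=covs,
                )
            cols = np.arange(col, col + basis.n_cols)
            term = TermInfo(
                f"s({','.join(covs)})",
                "smooth",
                cols,
                covs,
                basis=basis,
                penalty_index=len(self.penalties),
            )
            self.terms.append(term)
            self.penalties.append(Penalty(cols=cols, S=basis.penalty))
            col += basis.n_cols
        self.n_cols = col
        return self

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        X = np.zeros((n, self.n_cols))
        X[:, 0] = 1.0
        for term in self.terms:
            if term.kind == "factor":
                values = data[term.name].astype(str).to_numpy()
                for j, level in enumerate(term.levels[1:]):
                    X[:, term.cols[j]] = values == level
                unknown = ~np.isin(values, term.levels)
                if unknown.any():
                    raise ValidationError(
                        f"unknown level(s) {sorted(set(values[unknown]))} "
                        f"for factor {term.name!r}"
                    )
            elif term.kind == "smooth":
                coords = [data[c].to_numpy(float) for c in term.covariates]
                X[:, term.cols] = term.basis.design(*coords)
        return X

    def term(self, name: str) -> TermInfo:
        for t in self.terms:
            if t.name == name or (t.kind == "smooth" and name in (
                ",".join(t.covariates), t.covariates[0] if len(t.covariates) == 1 else None
            )):
                return t
        raise KeyError(f"no term named {name!r}; have {[t.name for t in self.terms]}")


# ---------------------------------------------------------------------------
# estimators


def _mixture_loglik(y, mu, p) -> float:
    """Observed-data log-likelihood of the ZIP mixture (p=None: Poisson)."""
    y = np.asarray(y, float)
    if p is None:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    zeros = y == 0
    ll = 0.0
    if zeros.any():
        ll += float(
            np.sum(np.log((1.0 - p[zeros]) + p[zeros] * np.exp(-mu[zeros])))
        )
    if (~zeros).any():
        yp, mup, pp = y[~zeros], mu[~zeros], p[~zeros]
        ll += float(
            np.sum(np.log(pp) + yp * np.log(mup) - mup - gammaln(yp + 1.0))
        )
    return ll


def _saturated_loglik(y) -> float:
    y = np.asarray(y, float)
    pos = y > 0
    return float(np.sum(y[pos] * np.log(y[pos]) - y[pos] - gammaln(y[pos] + 1.0)))


def _quad_penalty(beta, penalties, lambdas) -> float:
    q = 0.0
    for pen, lam in zip(penalties, lambdas):
        b = beta[pen.cols]
        q += lam * float(b @ pen.S @ b)
    return 0.5 * q


class _BaseCatchGAM(BaseEstimator):
    """Shared plumbing: design assembly, offsets, evidence-driven lambdas."""

    def _offset(self, X: pd.DataFrame) -> np.ndarray:
        if self.offset is None:
            return np.zeros(len(X))
        eff = X[self.offset].to_numpy(float)
        if np.any(eff <= 0):
            raise ValidationError("offset column must be strictly positive")
        return np.log(eff)

    def _validate_y(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        if np.any(y < 0):
            raise ValidationError("catch counts must be non-negative")
        return y

    def _select_lambdas(self, objective, n_pen: int) -> np.ndarray:
        """Coordinate-descent grid search maximizing the Laplace evidence."""
        if n_pen == 0:
            return np.zeros(0)
        if not self.select_lambdas:
            fixed = np.atleast_1d(np.asarray(self.lambdas, dtype=float))
            if fixed.size == 1:
                fixed = np.full(n_pen, fixed[0])
            return fixed
        lams = np.full(n_pen, 10.0)
        best = objective(lams)
        for _ in range(2):
            improved = False
            for j in range(n_pen):
                for val in LAMBDA_GRID:
                    if val == lams[j]:
                        continue
                    trial = lams.copy()
                    trial[j] = val
                    score = objective(trial)
                    if score > best + 1e-9:
                        best, lams, improved = score, trial, True
            if not improved:
                break
        return lams

    # -- reporting helpers shared by all model types ------------------------

    def _term_edf(self, fit: ComponentFit, design: _Design) -> dict:
        out = {}
        for term in design.terms:
            if term.kind == "intercept":
                continue
            out[term.name] = float(fit.edf_cols[term.cols].sum())
        return out

    def _term_ref_df(self, fit: ComponentFit, design: _Design) -> dict:
        out = {}
        for term in design.terms:
            if term.kind == "intercept":
                continue
            out[term.name] = float(fit.edf1_cols[term.cols].sum())
        return out

    def _finish_diagnostics(self, y, d_model, d_null, edf_total):
        n = len(y)
        self.deviance_ = d_model
        self.null_deviance_ = d_null
        self.dev_expl_ = 0.0 if d_null <= 0 else float(1.0 - d_model / d_null)
        denom = max(n - edf_total, 1.0)
        self.r2_adj_ = float(1.0 - (n - 1) / denom * (1.0 - self.dev_expl_))


FittedModel = Union["PoissonGAM", "ZeroInflatedGAM", "ConstrainedZeroInflatedGAM"]
"""A fitted estimator; carries coefficients, lambdas, edf, logE and diagnostics."""


class PoissonGAM(_BaseCatchGAM):
    """Poisson generalized additive model with a log-effort offset.

    Parameters
    ----------
    smooth_terms : sequence of (covariate(s), k)
        One entry per smooth; ``k`` is the thin-plate basis dimension
        (default 10 for 1-D, 25 for 2-D).  A plain string means default k.
    factor_terms : sequence of name or (name, reference)
        Categorical covariates; reference level defaults to ``"BV"`` when
        present.
    offset : str or None
        Column of X holding fishing effort (hooks); its log is the offset.
    """

    def __init__(
        self,
        smooth_terms=(),
        factor_terms=(),
        offset="effort_hooks",
        select_lambdas=True,
        lambdas=1.0,
        max_irls_iter=200,
    ):
        self.smooth_terms = smooth_terms
        self.factor_terms = factor_terms
        self.offset = offset
        self.select_lambdas = select_lambdas
        self.lambdas = lambdas
        self.max_irls_iter = max_irls_iter

    model_type = "GAM"

    def fit(self, X: pd.DataFrame, y):
        y = self._validate_y(y)
        off = self._offset(X)
        if np.all(y == 0):
            warnings.warn(
                "all-zero response: degenerate Poisson fit (intercept guarded)",
                RuntimeWarning,
            )
        design = _Design(self.smooth_terms, self.factor_terms).fit(X)
        Xc = design.transform(X)
        warm = {"beta": None}

        def objective(lams):
            f = fit_penalized_glm(
                y, Xc, design.penalties, lams, "poisson",
                offset=off, beta0=warm["beta"], max_iter=self.max_irls_iter,
            )
            warm["beta"] = f.beta
            return component_log_evidence(f, design.penalties, lams)

        lams = self._select_lambdas(objective, len(design.penalties))
        fit = fit_penalized_glm(
            y, Xc, design.penalties, lams, "poisson",
            offset=off, beta0=warm["beta"], max_iter=self.max_irls_iter,
        )

        self.design_ = design
        self.coef_ = fit.beta
        self.posterior_cov_ = fit.cov
        self.count_fit_ = fit
        self.lambdas_ = {
            f"count:{t.name}": lams[t.penalty_index]
            for t in design.terms
            if t.kind == "smooth"
        }
        self.edf_ = self._term_edf(fit, design)
        self.ref_df_ = self._term_ref_df(fit, design)
        self.edf_total_ = fit.edf_total
        self.log_evidence_ = component_log_evidence(fit, design.penalties, lams)
        self.n_em_iter_ = 0
        self.converged_ = fit.converged
        self.fitted_mu_ = fit.mu
        self.fitted_p_ = None
        self.notes_ = []

        # null (intercept-only) deviance for fit diagnostics
        null = fit_penalized_glm(
            y, np.ones((len(y), 1)), [], [], "poisson", offset=off
        )
        d_model = 2.0 * (_saturated_loglik(y) - _mixture_loglik(y, fit.mu, None))
        d_null = 2.0 * (_saturated_loglik(y) - _mixture_loglik(y, null.mu, None))
        self._finish_diagnostics(y, d_model, d_null, fit.edf_total)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected catch per cruise (includes the effort offset)."""
        eta = self.design_.transform(X) @ self.coef_ + self._offset(X)
        return np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))


class ZeroInflatedGAM(_BaseCatchGAM):
    """Zero-inflated Poisson GAM fitted by EM.

    The zero (regular-state probability) component has its own additive
    structure: by default it mirrors the count component's smooths and
    factors (``zero_terms="mirror"``).  The fitted attribute
    ``em_loglik_path_`` records the observed-data penalized log-likelihood
    at every EM iteration; it is non-decreasing.
    """

    def __init__(
        self,
        smooth_terms=(),
        factor_terms=(),
        offset="effort_hooks",
        zero_terms="mirror",
        select_lambdas=True,
        lambdas=1.0,
        max_em_iter=MAX_EM_ITER,
        em_tol=1e-6,
        search_em_iter=80,
        max_irls_iter=200,
    ):
        self.smooth_terms = smooth_terms
        self.factor_terms = factor_terms
        self.offset = offset
        self.zero_terms = zero_terms
        self.select_lambdas = select_lambdas
        self.lambdas = lambdas
        self.max_em_iter = max_em_iter
        self.em_tol = em_tol
        self.search_em_iter = search_em_iter
        self.max_irls_iter = max_irls_iter

    model_type = "ZIGAM"

    def _zero_design(self, design_c: _Design, X: pd.DataFrame):
        if self.zero_terms == "mirror":
            return design_c, None  # share the count design matrix
        smooths, factors = self.zero_terms
        dz = _Design(smooths, factors).fit(X)
        return dz, dz.transform(X)

    def fit(self, X: pd.DataFrame, y):
        y = self._validate_y(y)
        if not np.allclose(y, np.round(y)):
            raise ValidationError("ZIGAM requires integer counts")
        off = self._offset(X)
        design_c = _Design(self.smooth_terms, self.factor_terms).fit(X)
        Xc = design_c.transform(X)
        design_z, Xz = self._zero_design(design_c, X)
        if Xz is None:
            Xz = Xc
        self.notes_ = []

        if np.all(y > 0):
            # no zeros: the mixture degenerates to a plain Poisson GAM
            self.notes_.append(
                "response has no zeros: fell back to a Poisson GAM with p == 1"
            )
            gam = PoissonGAM(
                self.smooth_terms, self.factor_terms, self.offset,
                self.select_lambdas, self.lambdas, self.max_irls_iter,
            ).fit(X, y)
            self._adopt_gam(gam, len(y))
            return self

        pens_c = design_c.penalties
        pens_z = design_z.penalties
        n_pen = len(pens_c) + len(pens_z)
        warm = {"bc": None, "bz": None}

        def run_em(lams, max_em, tol, keep_warm=True):
            lam_c = lams[: len(pens_c)]
            lam_z = lams[len(pens_c):]
            z = np.where(y > 0, 1.0, 0.5)
            bc = warm["bc"] if keep_warm else None
            bz = warm["bz"] if keep_warm else None
            path = []
            prev = -np.inf
            converged = False
            cfit = zfit = None
            it = 0
            for it in range(1, max_em + 1):
                cfit = fit_penalized_glm(
                    y, Xc, pens_c, lam_c, "poisson", offset=off,
                    prior_weights=z, beta0=bc, max_iter=self.max_irls_iter,
                    tol=1e-12,
                )
                zfit = fit_penalized_glm(
                    z, Xz, pens_z, lam_z, "binomial", beta0=bz,
                    max_iter=self.max_irls_iter, tol=1e-12,
                )
                bc, bz = cfit.beta, zfit.beta
                mu = cfit.mu
                p = zfit.mu
                pll = (
                    _mixture_loglik(y, mu, p)
                    - _quad_penalty(bc, pens_c, lam_c)
                    - _quad_penalty(bz, pens_z, lam_z)
                )
                path.append(pll)
                if np.isfinite(prev) and abs(pll - prev) < tol * (abs(pll) + 1.0):
                    converged = True
                    break
                prev = pll
                # E-step: responsibility of the regular state for each zero
                z = np.where(
                    y > 0,
                    1.0,
                    p * np.exp(-mu) / ((1.0 - p) + p * np.exp(-mu)),
                )
            if keep_warm:
                warm["bc"], warm["bz"] = bc, bz
            return cfit, zfit, z, path, it, converged

        def evidence(cfit, zfit, path, lams):
            lam_c = lams[: len(pens_c)]
            lam_z = lams[len(pens_c):]
            le = path[-1]
            for pen, lam in zip(pens_c, lam_c):
                r, ld = pen.rank_and_logdet()
                if lam > 0 and r > 0:
                    le += 0.5 * (r * np.log(lam) + ld - r * np.log(2 * np.pi))
            for pen, lam in zip(pens_z, lam_z):
                r, ld = pen.rank_and_logdet()
                if lam > 0 and r > 0:
                    le += 0.5 * (r * np.log(lam) + ld - r * np.log(2 * np.pi))
            p_tot = cfit.beta.size + zfit.beta.size
            _, ld_c = np.linalg.slogdet(cfit.hessian)
            _, ld_z = np.linalg.slogdet(zfit.hessian)
            return le + 0.5 * p_tot * np.log(2 * np.pi) - 0.5 * (ld_c + ld_z)

        def objective(lams):
            cfit, zfit, _, path, _, _ = run_em(
                lams, self.search_em_iter, max(self.em_tol, 1e-5)
            )
            return evidence(cfit, zfit, path, lams)

        lams = self._select_lambdas(objective, n_pen)
        cfit, zfit, z, path, n_iter, converged = run_em(
            lams, self.max_em_iter, self.em_tol, keep_warm=False
        )

        lam_c = lams[: len(pens_c)]
        self.design_ = design_c
        self.zero_design_ = design_z
        self.coef_ = cfit.beta
        self.zero_coef_ = zfit.beta
        self.posterior_cov_ = cfit.cov
        self.zero_posterior_cov_ = zfit.cov
        self.count_fit_ = cfit
        self.zero_fit_ = zfit
        self.responsibilities_ = z
        self.lambdas_ = {}
        for t in design_c.terms:
            if t.kind == "smooth":
                self.lambdas_[f"count:{t.name}"] = lam_c[t.penalty_index]
        for t in design_z.terms:
            if t.kind == "smooth":
                self.lambdas_[f"zero:{t.name}"] = lams[len(pens_c) + t.penalty_index]
        self.edf_ = self._term_edf(cfit, design_c)
        self.ref_df_ = self._term_ref_df(cfit, design_c)
        self.edf_total_ = cfit.edf_total + zfit.edf_total
        self.em_loglik_path_ = np.array(path)
        self.n_em_iter_ = n_iter
        self.converged_ = converged
        self.log_evidence_ = evidence(cfit, zfit, path, lams)
        self.fitted_mu_ = cfit.mu
        self.fitted_p_ = zfit.mu

        # mixture deviance against an intercept-only mixture null
        null = ZeroInflatedGAM(
            offset=self.offset, select_lambdas=False, lambdas=0.0,
            max_em_iter=self.max_em_iter, em_tol=self.em_tol,
        )
        if self._is_null():
            d_null = d_model = 2.0 * (
                _saturated_loglik(y) - _mixture_loglik(y, cfit.mu, zfit.mu)
            )
        else:
            null.fit(X, y)
            d_model = 2.0 * (
                _saturated_loglik(y) - _mixture_loglik(y, cfit.mu, zfit.mu)
            )
            d_null = null.deviance_
        self._finish_diagnostics(y, d_model, d_null, self.edf_total_)
        return self

    def _is_null(self) -> bool:
        return not self.smooth_terms and not self.factor_terms

    def _adopt_gam(self, gam: PoissonGAM, n: int):
        for attr in (
            "design_", "coef_", "posterior_cov_", "count_fit_", "lambdas_",
            "edf_", "ref_df_", "edf_total_", "log_evidence_", "fitted_mu_",
            "deviance_", "null_deviance_", "dev_expl_", "r2_adj_",
        ):
            setattr(self, attr, getattr(gam, attr))
        self.zero_design_ = None
        self.zero_coef_ = np.array([ETA_CLIP])
        self.zero_posterior_cov_ = np.zeros((1, 1))
        self.fitted_p_ = np.full(n, expit(ETA_CLIP))
        self.responsibilities_ = np.ones(n)
        self.em_loglik_path_ = np.array([])
        self.n_em_iter_ = 0
        self.converged_ = True

    def predict_rate(self, X: pd.DataFrame) -> np.ndarray:
        """Regular-state Poisson mean (includes the effort offset)."""
        eta = self.design_.transform(X) @ self.coef_ + self._offset(X)
        return np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))

    def predict_zero_prob(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the regular (non-zero-inflated) state."""
        if self.zero_design_ is None:
            return np.full(len(X), expit(ETA_CLIP))
        return expit(self.zero_design_.transform(X) @ self.zero_coef_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected catch: p * mu."""
        return self.predict_zero_prob(X) * self.predict_rate(X)


class ConstrainedZeroInflatedGAM(ZeroInflatedGAM):
    """COZIGAM: the zero component is tied to the count component.

    The regular-state probability satisfies
    ``logit(p_i) = alpha + delta * log(mu_i)``, so the two processes are
    linearly related on their link scales.  ``alpha`` and ``delta`` are
    profiled inside the EM M-step: after the responsibility-weighted
    Poisson update, a two-parameter logistic regression of the
    responsibilities on log(mu) updates the linkage constants.
    """

    def __init__(
        self,
        smooth_terms=(),
        factor_terms=(),
        offset="effort_hooks",
        select_lambdas=True,
        lambdas=1.0,
        max_em_iter=MAX_EM_ITER,
        em_tol=1e-6,
        search_em_iter=80,
        max_irls_iter=200,
        fix_delta=None,
    ):
        super().__init__(
            smooth_terms=smooth_terms,
            factor_terms=factor_terms,
            offset=offset,
            zero_terms="constrained",
            select_lambdas=select_lambdas,
            lambdas=lambdas,
            max_em_iter=max_em_iter,
            em_tol=em_tol,
            search_em_iter=search_em_iter,
            max_irls_iter=max_irls_iter,
        )
        self.fix_delta = fix_delta

    model_type = "COZIGAM"

    def fit(self, X: pd.DataFrame, y):
        y = self._validate_y(y)
        if not np.allclose(y, np.round(y)):
            raise ValidationError("COZIGAM requires integer counts")
        off = self._offset(X)
        design_c = _Design(self.smooth_terms, self.factor_terms).fit(X)
        Xc = design_c.transform(X)
        self.notes_ = []
        if np.all(y > 0):
            self.notes_.append(
                "response has no zeros: fell back to a Poisson GAM with p == 1"
            )
            gam = PoissonGAM(
                self.smooth_terms, self.factor_terms, self.offset,
                self.select_lambdas, self.lambdas, self.max_irls_iter,
            ).fit(X, y)
            self._adopt_gam(gam, len(y))
            self.alpha_, self.delta_ = float(ETA_CLIP), 0.0
            return self

        pens_c = design_c.penalties
        warm = {"bc": None, "bz": None}

        def run_em(lams, max_em, tol, keep_warm=True):
            z = np.where(y > 0, 1.0, 0.5)
            bc = warm["bc"] if keep_warm else None
            bz = warm["bz"] if keep_warm else None
            path = []
            prev = -np.inf
            converged = False
            cfit = zfit = None
            lmu = None
            it = 0
            for it in range(1, max_em + 1):
                cfit = fit_penalized_glm(
                    y, Xc, pens_c, lams, "poisson", offset=off,
                    prior_weights=z, beta0=bc, max_iter=self.max_irls_iter,
                    tol=1e-12,
                )
                bc = cfit.beta
                lmu = cfit.eta  # log mu, clipped
                if self.fix_delta is None:
                    Xz = np.column_stack([np.ones_like(lmu), lmu])
                    zfit = fit_penalized_glm(
                        z, Xz, [], [], "binomial", beta0=bz,
                        max_iter=self.max_irls_iter, tol=1e-12,
                    )
                else:
                    Xz = np.ones((len(y), 1))
                    zfit = fit_penalized_glm(
                        z, Xz, [], [], "binomial",
                        offset=self.fix_delta * lmu, beta0=bz,
                        max_iter=self.max_irls_iter, tol=1e-12,
                    )
                bz = zfit.beta
                mu = cfit.mu
                p = zfit.mu
                pll = _mixture_loglik(y, mu, p) - _quad_penalty(bc, pens_c, lams)
                path.append(pll)
                if np.isfinite(prev) and abs(pll - prev) < tol * (abs(pll) + 1.0):
                    converged = True
                    break
                prev = pll
                z = np.where(
                    y > 0,
                    1.0,
                    p * np.exp(-mu) / ((1.0 - p) + p * np.exp(-mu)),
                )
            if keep_warm:
                warm["bc"], warm["bz"] = bc, bz
            return cfit, zfit, z, path, it, converged

        def evidence(cfit, zfit, path, lams):
            le = path[-1]
            for pen, lam in zip(pens_c, lams):
                r, ld = pen.rank_and_logdet()
                if lam > 0 and r > 0:
                    le += 0.5 * (r * np.log(lam) + ld - r * np.log(2 * np.pi))
            p_tot = cfit.beta.size + zfit.beta.size
            _, ld_c = np.linalg.slogdet(cfit.hessian)
            _, ld_z = np.linalg.slogdet(zfit.hessian)
            return le + 0.5 * p_tot * np.log(2 * np.pi) - 0.5 * (ld_c + ld_z)

        def objective(lams):
            cfit, zfit, _, path, _, _ = run_em(
                lams, self.search_em_iter, max(self.em_tol, 1e-5)
            )
            return evidence(cfit, zfit, path, lams)

        lams = self._select_lambdas(objective, len(pens_c))
        cfit, zfit, z, path, n_iter, converged = run_em(
            lams, self.max_em_iter, self.em_tol, keep_warm=False
        )

        self.design_ = design_c
        self.zero_design_ = None
        self.coef_ = cfit.beta
        self.zero_coef_ = zfit.beta
        self.alpha_ = float(zfit.beta[0])
        self.delta_ = (
            float(zfit.beta[1]) if self.fix_delta is None else float(self.fix_delta)
        )
        self.posterior_cov_ = cfit.cov
        self.zero_posterior_cov_ = zfit.cov
        self.count_fit_ = cfit
        self.zero_fit_ = zfit
        self.responsibilities_ = z
        self.lambdas_ = {
            f"count:{t.name}": lams[t.penalty_index]
            for t in design_c.terms if t.kind == "smooth"
        }
        self.edf_ = self._term_edf(cfit, design_c)
        self.ref_df_ = self._term_ref_df(cfit, design_c)
        self.edf_total_ = cfit.edf_total + zfit.beta.size
        self.em_loglik_path_ = np.array(path)
        self.n_em_iter_ = n_iter
        self.converged_ = converged
        self.log_evidence_ = evidence(cfit, zfit, path, lams)
        self.fitted_mu_ = cfit.mu
        self.fitted_p_ = zfit.mu

        d_model = 2.0 * (
            _saturated_loglik(y) - _mixture_loglik(y, cfit.mu, zfit.mu)
        )
        if self._is_null():
            d_null = d_model
        else:
            null = ConstrainedZeroInflatedGAM(
                offset=self.offset, select_lambdas=False, lambdas=0.0,
                fix_delta=0.0,
            ).fit(X, y)
            d_null = null.deviance_
        self._finish_diagnostics(y, d_model, d_null, self.edf_total_)
        return self

    def predict_zero_prob(self, X: pd.DataFrame) -> np.ndarray:
        lmu = np.clip(
            self.design_.transform(X) @ self.coef_ + self._offset(X),
            -ETA_CLIP, ETA_CLIP,
        )
        return expit(self.alpha_ + self.delta_ * lmu)


# ---------------------------------------------------------------------------
# spec-level functional interface


def _estimator_for(spec: ModelSpec, **overrides):
    kwargs = dict(
        smooth_terms=spec.smooth_terms,
        factor_terms=spec.factor_terms,
        offset=spec.offset,
    )
    if spec.model_type == "GAM":
        cls = PoissonGAM
    elif spec.model_type == "ZIGAM":
        cls = ZeroInflatedGAM
        kwargs["zero_terms"] = spec.zero_terms
    else:
        cls = ConstrainedZeroInflatedGAM
    kwargs.update(overrides)
    return cls(**kwargs)


def _fit_spec(spec: ModelSpec, data: pd.DataFrame, **overrides) -> FittedModel:
    est = _estimator_for(spec, **overrides)
    est.fit(data, data[spec.response].to_numpy(float))
    est.spec_ = spec
    return est


def fit_gam(spec: ModelSpec, data: pd.DataFrame, **overrides) -> FittedModel:
    """Fit a Poisson GAM described by ``spec`` to a cruise table."""
    if spec.model_type != "GAM":
        raise ValidationError("fit_gam requires model_type == 'GAM'")
    return _fit_spec(spec, data, **overrides)


def fit_zigam(spec: ModelSpec, data: pd.DataFrame, **overrides) -> FittedModel:
    """Fit a zero-inflated Poisson GAM by EM."""
    if spec.model_type != "ZIGAM":
        raise ValidationError("fit_zigam requires model_type == 'ZIGAM'")
    return _fit_spec(spec, data, **overrides)


def fit_cozigam(spec: ModelSpec, data: pd.DataFrame, **overrides) -> FittedModel:
    """Fit a constrained zero-inflated GAM (logit p linear in log mu)."""
    if spec.model_type != "COZIGAM":
        raise ValidationError("fit_cozigam requires model_type == 'COZIGAM'")
    return _fit_spec(spec, data, **overrides)


def log_marginal_likelihood(fit: FittedModel) -> float:
    """Laplace-approximated log marginal likelihood (logE) of a fitted model."""
    return float(fit.log_evidence_)


def summarize_fit(fit: FittedModel) -> pd.DataFrame:
    """Per-term Wald summary table plus overall fit statistics.

    One row per count-component term (smooths and factors): effective
    degrees of freedom, reference df, Wald chi-square against zero, and its
    p-value.  ``R2_adj`` and ``dev_expl`` are attached as DataFrame attrs
    and repeated on every row for flat serialization.
    """
    rows = []
    for term in fit.design_.terms:
        if term.kind == "intercept":
            continue
        beta = fit.coef_[term.cols]
        V = fit.posterior_cov_[np.ix_(term.cols, term.cols)]
        Vinv = np.linalg.pinv(V, rcond=1e-10)
        chisq = float(beta @ Vinv @ beta)
        edf = fit.edf_[term.name]
        ref_df = max(fit.ref_df_[term.name], edf)
        p = float(stats.chi2.sf(chisq, df=max(ref_df, 1e-6)))
        rows.append(
            {
                "term": term.name,
                "edf": edf,
                "ref_df": ref_df,
                "chi_sq": chisq,
                "p_value": p,
                "r2_adj": fit.r2_adj_,
                "dev_expl": fit.dev_expl_,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "edf", "ref_df", "chi_sq", "p_value", "r2_adj", "dev_expl"]
    )
    out.attrs["r2_adj"] = fit.r2_adj_
    out.attrs["dev_expl"] = fit.dev_expl_
    out.attrs["log_evidence"] = fit.log_evidence_
    return out


def predict_partial(
    fit: FittedModel, term: str, grid, conf: float = 0.95
) -> pd.DataFrame:
    """Centered partial effect of one count-component term on the link scale.

    Returns the effect with a Bayesian posterior +/- z * SE band.  For a
    smooth term ``grid`` is an array (1-D) or two arrays (2-D smooth); for
    a factor term ``grid`` is ignored and the non-reference levels are
    reported.
    """
    tinfo = fit.design_.term(term)
    z = stats.norm.ppf(0.5 + conf / 2.0)
    if tinfo.kind == "factor":
        beta = fit.coef_[tinfo.cols]
        V = fit.posterior_cov_[np.ix_(tinfo.cols, tinfo.cols)]
        se = np.sqrt(np.diag(V))
        return pd.DataFrame(
            {
                "level": tinfo.levels[1:],
                "effect": beta,
                "se": se,
                "lo": beta - z * se,
                "hi": beta + z * se,
            }
        )
    if tinfo.kind != "smooth":
        raise KeyError(f"term {term!r} has no partial effect")
    coords = grid if isinstance(grid, (tuple, list)) else (grid,)
    Xt = tinfo.basis.design(*coords)
    beta = fit.coef_[tinfo.cols]
    V = fit.posterior_cov_[np.ix_(tinfo.cols, tinfo.cols)]
    eff = Xt @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xt, V, Xt), 0.0))
    out = {}
    for name, c in zip(tinfo.covariates, coords):
        out[name] = np.asarray(c, float).ravel()
    out.update(
        {"effect": eff, "se": se, "lo": eff - z * se, "hi": eff + z * se,
         "extrapolated": tinfo.basis.extrapolation_mask(*coords)}
    )
    return pd.DataFrame(out)
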