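"""Binomial random-intercept models of perceived nuisance.

The response is the 0/1 tick "growth level L is a nuisance", modelled with a
logistic regression on growth level (continuous 1-5), respondent type, NEP
score and activity, plus a Gaussian random intercept per respondent to
absorb the dependence among one respondent's five answers:

    logit P(y_ij = 1 | b_i) = x_ij' beta + b_i,   b_i ~ N(0, sigma^2).

The marginal likelihood integrates the random intercepts out with a Laplace
approximation (per-respondent Newton inner optimisation plus second-order
correction); an adaptive Gauss-Hermite evaluation of the same marginal
likelihood is provided as a numerical cross-check.  Observation weights
(activity points / 100) enter the Bernoulli log-likelihood multiplicatively.

Model selection follows the "within 2 AIC units, take the simplest" rule,
terms are screened with Wald chi-square tests, and the median nuisance level
(the growth level at which the conditional nuisance probability is 50%,
an ED50) is estimated with a delta-method standard error, as the dose.p
function computes for a plain logistic fit.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "ModelSpec",
    "Ed50Estimate",
    "TermTest",
    "FitError",
    "BinomialRandomInterceptLogit",
    "fit_binomial_glmm",
    "aic_select",
    "term_tests",
    "estimate_ed50",
    "predict_probability",
    "gauss_hermite_loglik",
]

LOG_SIGMA_BOUNDS = (-7.0, 3.0)


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the optimizer trace."""


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms plus the random-intercept grouping.

    Terms name columns of the long nuisance table; ``a:b`` declares an
    interaction.  ``growth_level`` enters as a continuous covariate.
    """

    terms: tuple[str, ...]
    response: str = "nuisance"
    group_col: str = "respondent_id"
    weight_col: Optional[str] = None


@dataclass(frozen=True)
class Ed50Estimate:
    """Growth level at 50% conditional nuisance probability."""

    level: float
    se: float
    covariate_context: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class TermTest:
    term: str
    chisq: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

class _Design:
    """Treatment-coded design with intercept; remembers factor levels."""

    def __init__(self, terms: Sequence[str], data: Optional[pd.DataFrame] = None,
                 levels: Optional[dict[str, list]] = None):
        self.terms = tuple(terms)
        if levels is not None:
            self.levels = {k: list(v) for k, v in levels.items()}
            return
        self.levels = {}
        for term in self.terms:
            for part in term.split(":"):
                if part not in data.columns:
                    raise KeyError(f"term component {part!r} not in data")
                if not pd.api.types.is_numeric_dtype(data[part]):
                    self.levels[part] = sorted(data[part].astype(str).unique())

    def _part_block(self, data: pd.DataFrame, part: str) -> tuple[np.ndarray, list[str]]:
        if part in self.levels:
            lv = self.levels[part]
            vals = data[part].astype(str)
            unseen = set(vals.unique()) - set(lv)
            if unseen:
                raise ValueError(f"{part}: level(s) {sorted(unseen)} outside the fitted factor levels {lv}")
            cols = [(vals == l).to_numpy(float) for l in lv[1:]]
            names = [f"{part}[{l}]" for l in lv[1:]]
            return np.column_stack(cols) if cols else np.empty((len(data), 0)), names
        return data[part].to_numpy(float)[:, None], [part]

    def build(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
        blocks = [np.ones((len(data), 1))]
        names = ["Intercept"]
        slices: dict[str, list[int]] = {}
        pos = 1
        for term in self.terms:
            parts = term.split(":")
            block, bnames = self._part_block(data, parts[0])
            for part in parts[1:]:
                nb, nn = self._part_block(data, part)
                block = np.concatenate(
                    [block[:, [i]] * nb for i in range(block.shape[1])], axis=1)
                bnames = [f"{a}:{b}" for a in bnames for b in nn]
            blocks.append(block)
            names.extend(bnames)
            slices[term] = list(range(pos, pos + block.shape[1]))
            pos += block.shape[1]
        return np.concatenate(blocks, axis=1), names, slices


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

def _inner_modes(eta_fix, y, w, gidx, G, inv_s2, b0, tol=1e-11, max_iter=100):
    """Per-group Newton maximisation of the joint log-density over b.

    The penalised Bernoulli log-likelihood is strictly concave in each b_i,
    so undamped Newton converges; steps are clipped for numerical safety.
    """
    b = b0.copy()
    for _ in range(max_iter):
        eta = eta_fix + b[gidx]
        mu = expit(eta)
        grad = np.bincount(gidx, weights=w * (y - mu), minlength=G) - b * inv_s2
        hess = np.bincount(gidx, weights=w * mu * (1.0 - mu), minlength=G) + inv_s2
        step = grad / hess
        np.clip(step, -4.0, 4.0, out=step)
        b += step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta_fix + b[gidx]
    mu = expit(eta)
    hess = np.bincount(gidx, weights=w * mu * (1.0 - mu), minlength=G) + inv_s2
    return b, eta, hess


def _bernoulli_ll(eta, y, w):
    # sum w * (y*eta - log(1 + e^eta)), stable at large |eta|
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _laplace_loglik(params, X, y, w, gidx, G, warm_b):
    beta, log_sigma = params[:-1], params[-1]
    inv_s2 = np.exp(-2.0 * log_sigma)
    eta_fix = X @ beta
    b, eta, hess = _inner_modes(eta_fix, y, w, gidx, G, inv_s2, warm_b)
    warm_b[:] = b
    ll = (_bernoulli_ll(eta, y, w)
          - 0.5 * inv_s2 * float(b @ b)
          - G * log_sigma
          - 0.5 * float(np.sum(np.log(hess))))
    return ll


def gauss_hermite_loglik(beta, sigma, X, y, w, groups, n_points: int = 30) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood at fixed parameters.

    Quadrature nodes are centred at each respondent's posterior mode and
    scaled by the inverse curvature there, so a handful of nodes suffices;
    with >= 30 nodes this serves as a near-exact reference for the Laplace
    approximation.
    """
    gidx, G = _group_codes(groups)
    beta = np.asarray(beta, float)
    sigma = max(float(sigma), 1e-8)
    inv_s2 = sigma ** -2
    eta_fix = X @ beta
    b_hat, _, hess = _inner_modes(eta_fix, y, w, gidx, G, inv_s2, np.zeros(G))
    z, wq = hermgauss(n_points)
    scale = np.sqrt(2.0 / hess)  # (G,)
    # log integrand pieces per node, accumulated per group
    log_terms = np.empty((G, n_points))
    for k in range(n_points):
        b_k = b_hat + scale * z[k]
        eta = eta_fix + b_k[gidx]
        ll_g = np.bincount(gidx, weights=w * (y * eta - np.logaddexp(0.0, eta)), minlength=G)
        log_g = ll_g - 0.5 * inv_s2 * b_k ** 2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
        log_terms[:, k] = np.log(wq[k]) + z[k] ** 2 + log_g
    m = log_terms.max(axis=1, keepdims=True)
    group_ll = m[:, 0] + np.log(np.sum(np.exp(log_terms - m), axis=1)) + np.log(scale)
    return float(np.sum(group_ll))


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups), sort=False)
    return codes.astype(np.int64), len(uniques)


def _fingerprint(y, groups, w) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(np.asarray(y, float)).tobytes())
    h.update(np.ascontiguousarray(pd.factorize(np.asarray(groups))[0]).tobytes())
    h.update(np.ascontiguousarray(np.asarray(w, float)).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class BinomialRandomInterceptLogit(BaseEstimator):
    """Logistic regression with one Gaussian random intercept per group.

    scikit-learn style estimator: parameters in ``__init__``, data in
    ``fit(X, y, groups=..., sample_weight=...)``, fitted state in
    trailing-underscore attributes.

    Parameters
    ----------
    terms : tuple of str
        Fixed-effect terms, naming columns of ``X``; ``a:b`` is an
        interaction.  Non-numeric columns are treatment-coded against their
        first (sorted) level.
    tol : float
        Relative log-likelihood convergence tolerance of the outer
        quasi-Newton optimisation over (beta, log sigma).
    max_iter : int
        Outer iteration cap.

    Attributes
    ----------
    coef_, coef_names_ : fixed-effect estimates (intercept first).
    cov_ : covariance matrix of the fixed effects.
    sigma_ : random-intercept standard deviation.
    loglik_, aic_, n_params_ : Laplace log-likelihood and AIC
        (-2 loglik + 2k, k = fixed effects + 1 variance parameter).
    converged_, separation_flag_ : diagnostics.
    """

    def __init__(self, terms: Sequence[str] = ("growth_level",), tol: float = 1e-12,
                 max_iter: int = 500):
        self.terms = terms
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting ------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y, groups=None, sample_weight=None):
        if groups is None:
            raise ValueError("groups (respondent ids) are required")
        y = np.asarray(y, float)
        if len(X) == 0:
            raise ValueError("empty data")
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        if np.any(w <= 0) or np.any(w > 1.0 + 1e-12):
            raise ValueError("weights must lie in (0, 1]")
        self._design_ = _Design(self.terms, X)
        Xm, names, slices = self._design_.build(X)
        gidx, G = _group_codes(groups)

        # starting values: sigma -> 0 limit is an ordinary weighted GLM
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, Xm, family=sm.families.Binomial(), var_weights=w)
            beta0 = glm.fit().params
        x0 = np.concatenate([beta0, [0.0]])

        warm_b = np.zeros(G)
        nll = lambda p: -_laplace_loglik(p, Xm, y, w, gidx, G, warm_b)
        bounds = [(None, None)] * Xm.shape[1] + [LOG_SIGMA_BOUNDS]
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                jac="3-point",
                                options={"maxiter": self.max_iter,
                                         "ftol": self.tol, "gtol": 1e-8})
        if not res.success and "ROUNDING" not in str(res.message).upper():
            raise FitError(f"GLMM optimizer did not converge: {res.message!r} "
                           f"(nit={res.nit}, fun={res.fun:.6g}, x={res.x})")

        p = Xm.shape[1]
        self.coef_ = res.x[:p]
        self.log_sigma_ = float(res.x[-1])
        self.sigma_ = float(np.exp(self.log_sigma_))
        self.loglik_ = -float(res.fun)
        self.n_params_ = p + 1
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.n_params_
        self.coef_names_ = names
        self.term_slices_ = slices
        self.converged_ = True
        self.separation_flag_ = bool(np.max(np.abs(self.coef_)) > 15
                                     or np.max(np.abs(Xm @ self.coef_)) > 30)

        hess = approx_hess1(res.x, nll)
        full_cov = self._safe_inverse(hess)
        self.cov_ = full_cov[:p, :p]
        self.cov_log_sigma_ = float(full_cov[-1, -1])
        self.n_obs_ = len(y)
        self.n_groups_ = G
        self.classes_ = np.array([0, 1])
        self.data_fingerprint_ = _fingerprint(y, groups, w)
        return self

    @staticmethod
    def _safe_inverse(hess: np.ndarray) -> np.ndarray:
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        # symmetrise against finite-difference noise
        cov = 0.5 * (cov + cov.T)
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 0.0, None)
        return (evecs * evals) @ evecs.T

    # -- prediction ----------------------------------------------------------
    def linear_predictor(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Conditional (b=0) linear predictor and its rows of the design."""
        Xm, _, _ = self._design_.build(X)
        return Xm @ self.coef_, Xm

    def predict_nuisance_probability(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(X)[0])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_nuisance_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_nuisance_probability(X) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------

def fit_binomial_glmm(data: pd.DataFrame, spec: ModelSpec,
                      tol: float = 1e-10, max_iter: int = 500) -> BinomialRandomInterceptLogit:
    """Fit the random-intercept logistic model described by ``spec``."""
    if len(data) == 0:
        raise ValueError("empty data")
    w = None if spec.weight_col is None else data[spec.weight_col].to_numpy(float)
    est = BinomialRandomInterceptLogit(terms=tuple(spec.terms), tol=tol, max_iter=max_iter)
    est.fit(data, data[spec.response].to_numpy(float),
            groups=data[spec.group_col].to_numpy(), sample_weight=w)
    est.spec_ = spec
    return est


def aic_select(fits: Sequence[BinomialRandomInterceptLogit]) -> BinomialRandomInterceptLogit:
    """AIC selection with the "delta AIC within 2 takes the simplest" rule.

    ``fits`` must be ordered simplest-first and fitted to the same data; the
    first candidate whose AIC is within 2 units of the minimum wins.
    """
    if len(fits) < 2:
        raise ValueError("need at least two candidate fits")
    fps = {f.data_fingerprint_ for f in fits}
    if len(fps) != 1:
        raise ValueError("candidate fits were not fitted to the same data")
    best = min(f.aic_ for f in fits)
    for f in fits:
        if f.aic_ - best <= 2.0:
            return f
    raise AssertionError("unreachable")  # pragma: no cover


def term_tests(fit: BinomialRandomInterceptLogit) -> list[TermTest]:
    """Wald chi-square test per fixed-effect term.

    W = beta_t' V_t^{-1} beta_t with V_t the covariance sub-block of the
    term's coefficients; df = number of coefficients in the term.
    """
    out = []
    for term, idx in fit.term_slices_.items():
        beta_t = fit.coef_[idx]
        V_t = fit.cov_[np.ix_(idx, idx)]
        try:
            sol = np.linalg.solve(V_t, beta_t)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular covariance sub-block for term {term!r}") from exc
        W = float(beta_t @ sol)
        df = len(idx)
        out.append(TermTest(term=term, chisq=W, df=df, p_value=float(chi2.sf(W, df))))
    return out


def _context_rows(fit: BinomialRandomInterceptLogit, covariate_context: Mapping[str, object]):
    """Design rows at growth level 0 and 1 under the given context."""
    needed = {p for t in fit.term_slices_ for p in t.split(":")}
    needed.discard("growth_level")
    missing = needed - set(covariate_context)
    if missing:
        raise ValueError(f"covariate_context missing {sorted(missing)}")
    base = {k: [v] for k, v in covariate_context.items()}
    row0 = pd.DataFrame({**base, "growth_level": [0.0]})
    row1 = pd.DataFrame({**base, "growth_level": [1.0]})
    x0 = fit._design_.build(row0)[0][0]
    x1 = fit._design_.build(row1)[0][0]
    return x0, x1 - x0


def estimate_ed50(fit: BinomialRandomInterceptLogit,
                  covariate_context: Optional[Mapping[str, object]] = None) -> Ed50Estimate:
    """Median nuisance level with a delta-method standard error.

    The level solves x0'beta + L * s'beta = 0 with x0 the design row at
    growth level 0 under ``covariate_context`` and s the per-level contrast
    (this reduces to -beta0/beta_level in the simplest model, exactly what
    dose.p computes at p = 0.5); Var(ED50) ~= g' V g with g the gradient of
    -x0'beta / s'beta.
    """
    covariate_context = dict(covariate_context or {})
    x0, xs = _context_rows(fit, covariate_context)
    a = float(x0 @ fit.coef_)
    s = float(xs @ fit.coef_)
    if abs(s) < 1e-8:
        raise ZeroDivisionError("growth-level slope is zero; median nuisance level undefined")
    level = -a / s
    g = -x0 / s + (a / s ** 2) * xs
    var = float(g @ fit.cov_ @ g)
    return Ed50Estimate(level=level, se=float(np.sqrt(max(var, 0.0))),
                        covariate_context=covariate_context)


def predict_probability(fit: BinomialRandomInterceptLogit, grid: pd.DataFrame,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Conditional (b=0) nuisance probabilities with delta-method CIs.

    The interval is computed on the logit scale and transformed, so it stays
    inside (0, 1).
    """
    eta, Xm = fit.linear_predictor(grid)
    se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xm, fit.cov_, Xm), 0.0))
    zq = norm.ppf(1.0 - alpha / 2.0)
    out = grid.copy()
    out["probability"] = expit(eta)
    out["ci_low"] = expit(eta - zq * se_eta)
    out["ci_high"] = expit(eta + zq * se_eta)
    return out
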