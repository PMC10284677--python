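"""Random-intercept generalized linear mixed models via adaptive Gauss-Hermite.

A single scalar Gaussian random intercept per grouping unit (the sample donor)
is integrated out of the marginal likelihood with adaptive Gauss-Hermite
quadrature: for every group the integrand is re-centered at its posterior mode
and re-scaled by its curvature, which keeps a handful of nodes accurate even
when the conditional posterior is much narrower than the random-effect prior.
One node recovers the Laplace approximation.

The gaussian-identity family has a closed-form marginal likelihood and is
delegated to statsmodels' linear mixed model (ML); all other families use the
quadrature engine below. Inference is by Wald tests on the fixed effects, with
standard errors from a finite-difference Hessian of the marginal deviance.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp, ndtri

from .families import Family, get_family, squeeze_proportions

logger = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)
_LOG_SIGMA_BOUNDS = (-5.0, 3.0)

FAMILIES = ("negative_binomial", "poisson", "beta", "binomial_logit",
            "proportional_odds", "gaussian_identity")


@dataclass
class ModelFit:
    """One fitted random-intercept model."""

    params: np.ndarray
    names: list
    bse: np.ndarray
    pvalues: np.ndarray
    vcov: np.ndarray            # fixed-effects block of the covariance
    loglik: float
    sigma2_b: float
    dispersion: dict
    converged: bool
    n_obs: int
    n_groups: int
    method: str = "agq"
    reason: str = ""
    downgraded: bool = False
    term_slices: dict = field(default_factory=dict)

    def coef(self, name):
        return self.params[self.names.index(name)]

    def se(self, name):
        return self.bse[self.names.index(name)]

    def pvalue(self, name):
        if not self.converged:
            return np.nan
        return self.pvalues[self.names.index(name)]

    def wald_term(self, term):
        """Joint Wald chi-square p-value for all columns of a model term."""
        if not self.converged:
            return np.nan
        idx = self.term_slices.get(term)
        if idx is None:
            idx = [self.names.index(term)]
        idx = np.asarray(idx)
        b = self.params[idx]
        V = self.vcov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            return np.nan
        if chi2 < 0:
            return np.nan
        return float(stats.chi2.sf(chi2, df=len(idx)))


def _group_codes(groups):
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes.astype(np.intp), len(uniques)


class _AGQObjective:
    """Negative marginal log-likelihood and frozen-node analytic gradient."""

    def __init__(self, y, X, gidx, n_groups, family: Family, n_points: int,
                 offset=None):
        self.y = y
        self.X = X
        self.g = gidx
        self.G = n_groups
        self.fam = family
        self.p = X.shape[1]
        self.offset = np.zeros(len(y)) if offset is None else offset
        z, w = np.polynomial.hermite.hermgauss(n_points)
        self.z = z
        self.logw = np.log(w) + z ** 2
        self.modes = np.zeros(n_groups)

    def _find_modes(self, eta0, aux, sigma2):
        """Vectorized per-group Newton / Fisher-scoring for the posterior modes."""
        m = self.modes.copy()
        for _ in range(30):
            eta = eta0 + m[self.g]
            d1 = self.fam.d1(self.y, eta, aux)
            d2 = self.fam.d2(self.y, eta, aux)
            score = np.bincount(self.g, weights=d1, minlength=self.G) - m / sigma2
            hess = np.bincount(self.g, weights=d2, minlength=self.G) - 1.0 / sigma2
            step = -score / hess
            step = np.clip(step, -2.0, 2.0)
            m += step
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = eta0 + m[self.g]
        d2 = self.fam.d2(self.y, eta, aux)
        hess = np.bincount(self.g, weights=d2, minlength=self.G) - 1.0 / sigma2
        self.modes = m
        return m, np.sqrt(-1.0 / hess)

    def _split(self, theta):
        return theta[:self.p], theta[self.p], theta[self.p + 1:]

    def freeze(self, theta):
        """Re-center the quadrature nodes at the current posterior modes."""
        beta, log_sigma, aux = self._split(theta)
        eta0 = self.X @ beta + self.offset
        self._m, self._h = self._find_modes(eta0, aux, np.exp(2 * log_sigma))

    def frozen_value_and_grad(self, theta):
        """Negative log-likelihood with the nodes held fixed.

        With fixed nodes the analytic gradient is exact, so the inner
        optimizer sees a consistent objective; an outer loop re-freezes the
        nodes until self-consistency, at which point the frozen optimum
        coincides with the adaptive-quadrature one (the quadrature value is
        insensitive to node placement once the nodes sit at the modes).
        """
        beta, log_sigma, aux = self._split(theta)
        sigma2 = np.exp(2 * log_sigma)
        eta0 = self.X @ beta + self.offset
        m, h = self._m, self._h
        b = m[:, None] + _SQRT2 * h[:, None] * self.z[None, :]      # G x K
        eta = eta0[:, None] + b[self.g, :]                           # J x K
        ll = self.fam.loglik(self.y[:, None], eta, aux)              # J x K
        ll_g = np.zeros((self.G, ll.shape[1]))
        np.add.at(ll_g, self.g, ll)
        log_prior = -b ** 2 / (2.0 * sigma2) - log_sigma \
            - 0.5 * np.log(2 * np.pi)
        t = self.logw[None, :] + np.log(_SQRT2 * h)[:, None] + ll_g + log_prior
        ll_i = logsumexp(t, axis=1)
        nll = -float(np.sum(ll_i))

        pw = np.exp(t - ll_i[:, None])                               # G x K
        d1 = self.fam.d1(self.y[:, None], eta, aux)                  # J x K
        obs_w = pw[self.g, :]
        g_beta = self.X.T @ np.sum(obs_w * d1, axis=1)
        g_logsigma = float(np.sum(pw * (b ** 2 / sigma2 - 1.0)))
        if self.fam.n_aux:
            da = self.fam.d_aux(self.y[:, None], eta, aux)           # J x K x A
            g_aux = np.einsum("jk,jka->a", obs_w, da)
        else:
            g_aux = np.zeros(0)
        grad = -np.concatenate([g_beta, [g_logsigma], g_aux])
        return nll, grad

    def value_and_grad(self, theta):
        """Adaptive value and gradient: nodes re-found at this theta."""
        self.freeze(theta)
        return self.frozen_value_and_grad(theta)

    def laplace_value(self, theta):
        """Exact Laplace (1-node) marginal negative log-likelihood."""
        beta, log_sigma, aux = self._split(theta)
        sigma2 = np.exp(2 * log_sigma)
        eta0 = self.X @ beta + self.offset
        m, h = self._find_modes(eta0, aux, sigma2)
        eta = eta0 + m[self.g]
        ll_g = np.bincount(self.g, weights=self.fam.loglik(self.y, eta, aux),
                           minlength=self.G)
        ll_i = ll_g - m ** 2 / (2 * sigma2) - log_sigma + np.log(h)
        return -float(np.sum(ll_i))


def _hessian_from_values(fun, x, rel_step=1e-4):
    """Central second differences of a scalar function."""
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            fij = fun(x + ei + ej)
            fi = fun(x + ei - ej)
            fj = fun(x - ei + ej)
            fmj = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fij - fi - fj + fmj) / (4 * h[i] * h[j])
    return H


def _numeric_hessian(fun, x, rel_step=1e-4):
    """Central finite differences of a gradient-returning function."""
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        h = rel_step * (1.0 + abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        _, gp = fun(xp)
        _, gm = fun(xm)
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _start_values(y, X, family, gidx, n_groups):
    eta0 = family.init_eta(np.asarray(y, dtype=float))
    if family.name == "proportional_odds":
        beta = np.zeros(X.shape[1])
        mu = None
    else:
        beta, *_ = np.linalg.lstsq(X, eta0, rcond=None)
        mu = np.exp(X @ beta) if family.name in ("poisson", "negative_binomial") \
            else None
    if mu is None:
        mu = np.full(len(y), np.mean(y))
    aux = family.init_aux(np.asarray(y, dtype=float), mu)
    return np.concatenate([beta, [-1.0], aux])


def _fit_agq(y, X, gidx, n_groups, family, n_points, names, term_slices,
             offset=None, start=None):
    obj = _AGQObjective(y, X, gidx, n_groups, family, n_points, offset)
    p = X.shape[1]
    if start is None:
        start = _start_values(y, X, family, gidx, n_groups)
    bounds = ([(None, None)] * p + [_LOG_SIGMA_BOUNDS] + family.aux_bounds())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_points == 1:
            # true Laplace; numeric gradient (fallback rung, cost is fine)
            res = optimize.minimize(obj.laplace_value, start,
                                    method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 300, "ftol": 1e-11})
            theta = res.x
            converged_path = bool(res.success)
        else:
            # outer loop: freeze nodes, optimize exactly, re-freeze
            theta = start.copy()
            converged_path = False
            for _ in range(15):
                obj.freeze(theta)
                res = optimize.minimize(obj.frozen_value_and_grad, theta,
                                        jac=True, method="L-BFGS-B",
                                        bounds=bounds,
                                        options={"maxiter": 200,
                                                 "ftol": 1e-11,
                                                 "gtol": 1e-7})
                step = np.max(np.abs(res.x - theta))
                theta = res.x
                if step < 1e-7:
                    converged_path = bool(res.success)
                    break
    nll, grad = obj.value_and_grad(theta)
    gnorm = np.max(np.abs(grad[:p]))
    ok = converged_path or gnorm < 1e-2 * (1.0 + abs(nll))
    if n_points == 1:
        H = _hessian_from_values(obj.laplace_value, theta)
    else:
        H = _numeric_hessian(obj.value_and_grad, theta)
    try:
        V = np.linalg.inv(H)
        diag = np.diag(V)
        if np.any(~np.isfinite(diag[:p])) or np.any(diag[:p] <= 0):
            ok = False
            V = np.full_like(H, np.nan)
    except np.linalg.LinAlgError:
        ok = False
        V = np.full_like(H, np.nan)
    bse = np.sqrt(np.abs(np.diag(V)[:p]))
    z = theta[:p] / bse
    pvals = 2 * stats.norm.sf(np.abs(z))
    sigma2_b = float(np.exp(2 * theta[p]))
    disp = {n: float(v) for n, v in zip(family.aux_names, theta[p + 1:])}
    fit = ModelFit(params=theta[:p], names=list(names), bse=bse,
                   pvalues=pvals if ok else np.full(p, np.nan),
                   vcov=V[:p, :p], loglik=-nll, sigma2_b=sigma2_b,
                   dispersion=disp, converged=ok, n_obs=len(y),
                   n_groups=n_groups,
                   method=f"agq{n_points}" if n_points > 1 else "laplace",
                   term_slices=dict(term_slices))
    return fit


def _fit_glm_fallback(y, X, family, names, term_slices, offset=None):
    """Fixed-effects-only fit (no random intercept), flagged as a downgrade."""

    def vg(theta):
        beta = theta[:X.shape[1]]
        aux = theta[X.shape[1]:]
        eta = X @ beta + (offset if offset is not None else 0.0)
        ll = family.loglik(y, eta, aux)
        d1 = family.d1(y, eta, aux)
        g_beta = X.T @ d1
        g_aux = family.d_aux(y, eta, aux).sum(axis=0) if family.n_aux else np.zeros(0)
        return -float(np.sum(ll)), -np.concatenate([g_beta, g_aux])

    p = X.shape[1]
    start = _start_values(y, X, family, None, 0)
    start = np.concatenate([start[:p], start[p + 1:]])   # drop log_sigma
    bounds = [(None, None)] * p + family.aux_bounds()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(vg, start, jac=True, method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": 300})
    theta = res.x
    H = _numeric_hessian(vg, theta)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.full_like(H, np.nan)
    bse = np.sqrt(np.abs(np.diag(V)[:p]))
    pvals = 2 * stats.norm.sf(np.abs(theta[:p] / bse))
    nll, _ = vg(theta)
    disp = {n: float(v) for n, v in zip(family.aux_names, theta[p:])}
    return ModelFit(params=theta[:p], names=list(names), bse=bse, pvalues=pvals,
                    vcov=V[:p, :p], loglik=-nll, sigma2_b=0.0, dispersion=disp,
                    converged=bool(res.success), n_obs=len(y), n_groups=0,
                    method="glm", downgraded=True, term_slices=dict(term_slices))


def _fit_gaussian(y, X, groups, names, term_slices):
    import statsmodels.api as sm

    gidx, n_groups = _group_codes(groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=gidx)
        try:
            res = model.fit(reml=False, method="lbfgs")
        except Exception as exc:  # pragma: no cover - rare numerical failure
            logger.warning("MixedLM failed (%s); falling back to OLS", exc)
            ols = sm.OLS(y, X).fit()
            return ModelFit(params=np.asarray(ols.params), names=list(names),
                            bse=np.asarray(ols.bse),
                            pvalues=np.asarray(ols.pvalues),
                            vcov=np.asarray(ols.cov_params()),
                            loglik=float(ols.llf), sigma2_b=0.0,
                            dispersion={"sigma2": float(ols.scale)},
                            converged=True, n_obs=len(y), n_groups=n_groups,
                            method="ols", downgraded=True,
                            term_slices=dict(term_slices))
    p = X.shape[1]
    params = np.asarray(res.fe_params)
    bse = np.asarray(res.bse_fe)
    z = params / bse
    pvals = 2 * stats.norm.sf(np.abs(z))
    sigma2_b = float(np.asarray(res.cov_re).ravel()[0])
    return ModelFit(params=params, names=list(names), bse=bse, pvalues=pvals,
                    vcov=np.asarray(res.cov_params())[:p, :p],
                    loglik=float(res.llf), sigma2_b=max(sigma2_b, 0.0),
                    dispersion={"sigma2": float(res.scale)},
                    converged=bool(res.converged), n_obs=len(y),
                    n_groups=n_groups, method="mixedlm",
                    term_slices=dict(term_slices))


def fit_random_intercept(y, X, groups, family, *, names=None, term_slices=None,
                         n_points=10, offset=None, n_levels=None):
    """Fit a single-feature random-intercept model.

    Parameters
    ----------
    y : array of responses (one feature).
    X : fixed-effects design matrix (no intercept column for the
        proportional-odds family).
    groups : per-observation individual labels.
    family : one of ``FAMILIES``.
    names : column names of X.
    term_slices : mapping term -> list of column indices, for joint Wald tests
        of multi-column (factor) terms.
    n_points : adaptive Gauss-Hermite nodes; 1 = Laplace.
    offset : optional per-observation offset on the linear-predictor scale
        (count families only; e.g. log sequencing depth).

    Non-convergence walks a retry ladder: perturbed restart, then Laplace,
    then a fixed-effects-only GLM flagged as downgraded.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if term_slices is None:
        term_slices = {n: [i] for i, n in enumerate(names)}
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    n_obs = len(y)
    if n_obs != X.shape[0]:
        raise ValueError("y and X have mismatched lengths")
    if np.all(y == y[0]):
        return ModelFit(params=np.full(p, np.nan), names=list(names),
                        bse=np.full(p, np.nan), pvalues=np.full(p, np.nan),
                        vcov=np.full((p, p), np.nan), loglik=np.nan,
                        sigma2_b=np.nan, dispersion={}, converged=False,
                        n_obs=n_obs, n_groups=0, reason="degenerate response",
                        term_slices=dict(term_slices))
    if np.linalg.matrix_rank(X) < p:
        return ModelFit(params=np.full(p, np.nan), names=list(names),
                        bse=np.full(p, np.nan), pvalues=np.full(p, np.nan),
                        vcov=np.full((p, p), np.nan), loglik=np.nan,
                        sigma2_b=np.nan, dispersion={}, converged=False,
                        n_obs=n_obs, n_groups=0, reason="rank_deficient",
                        term_slices=dict(term_slices))

    if family == "gaussian_identity":
        return _fit_gaussian(y, X, groups, names, term_slices)

    fam = get_family(family, n_levels=n_levels)
    fam.validate(y)
    gidx, n_groups = _group_codes(groups)
    if n_groups < 2:
        raise ValueError("grouping factor must have >= 2 groups")

    fit = _fit_agq(y, X, gidx, n_groups, fam, n_points, names, term_slices,
                   offset=offset)
    if fit.converged:
        return fit
    # rung 1: perturbed restart
    start = _start_values(y, X, fam, gidx, n_groups)
    rng = np.random.default_rng(0)
    start = start + rng.normal(0.0, 0.1, size=start.shape)
    fit2 = _fit_agq(y, X, gidx, n_groups, fam, n_points, names, term_slices,
                    offset=offset, start=start)
    if fit2.converged:
        fit2.reason = "restarted"
        return fit2
    # rung 2: Laplace
    fit3 = _fit_agq(y, X, gidx, n_groups, fam, 1, names, term_slices,
                    offset=offset)
    if fit3.converged:
        fit3.reason = "laplace_fallback"
        fit3.downgraded = True
        return fit3
    # rung 3: fixed effects only
    logger.warning("random-intercept fit failed; downgrading to plain GLM")
    fit4 = _fit_glm_fallback(y, X, fam, names, term_slices, offset=offset)
    fit4.reason = "glm_fallback"
    return fit4


def normalize_continuous(values):
    """Rank-based inverse-normal transform (Blom offset, mean ranks for ties)."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 3:
        raise ValueError("rank-normal transform needs >= 3 distinct values")
    n = len(values)
    r = stats.rankdata(values, method="average")
    return ndtri((r - 3.0 / 8.0) / (n + 0.25))


def posthoc_pairwise(fit: ModelFit, time_term: str, levels):
    """All pairwise time-level contrasts on the linear-predictor scale.

    Time must be coded with treatment contrasts against the first level; the
    contrast (level_b, level_a) estimates the linear-predictor difference
    b - a, with a Wald z test from the fitted covariance.
    """
    if not fit.converged:
        return []
    idx = fit.term_slices.get(time_term, [])
    levels = list(levels)
    L = len(levels)
    if len(idx) != L - 1:
        raise ValueError("time term columns do not match the level count")
    p = len(fit.params)
    out = []
    for a in range(L):
        for b_ in range(a + 1, L):
            c = np.zeros(p)
            if b_ > 0:
                c[idx[b_ - 1]] += 1.0
            if a > 0:
                c[idx[a - 1]] -= 1.0
            est = float(c @ fit.params)
            var = float(c @ fit.vcov @ c)
            if var <= 0 or not np.isfinite(var):
                pv = np.nan
            else:
                pv = 2 * stats.norm.sf(abs(est) / np.sqrt(var))
            out.append(((levels[a], levels[b_]), est, pv))
    return out


__all__ = ["ModelFit", "fit_random_intercept", "normalize_continuous",
           "posthoc_pairwise", "squeeze_proportions", "FAMILIES"]
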