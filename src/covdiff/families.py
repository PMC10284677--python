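"""Exponential-family (and ordinal) log-likelihoods for random-intercept models.

Each family exposes the observation-level log-likelihood and its first two
derivatives with respect to the linear predictor eta, plus derivatives with
respect to any auxiliary parameters (dispersion, precision, cutpoints). The
auxiliary parameters are always carried on an unconstrained scale (log for
positive quantities) so the optimizer can run box-free.
"""
from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln, polygamma

_LOG_EPS = 1e-12


def _trigamma(x):
    return polygamma(1, x)


class Family:
    """Base class; subclasses implement per-observation log-likelihood pieces."""

    name: str = "base"
    n_aux: int = 0          # number of auxiliary (non-eta) parameters
    aux_names: tuple = ()

    def loglik(self, y, eta, aux):
        raise NotImplementedError

    def d1(self, y, eta, aux):
        """d loglik / d eta."""
        raise NotImplementedError

    def d2(self, y, eta, aux):
        """d2 loglik / d eta^2 (or negative expected information)."""
        raise NotImplementedError

    def d_aux(self, y, eta, aux):
        """Per-observation gradient w.r.t. the unconstrained aux parameters.

        Returns an array of shape y.shape + (n_aux,); default: numeric.
        """
        shape = np.broadcast_shapes(np.shape(y), np.shape(eta))
        if self.n_aux == 0:
            return np.zeros(shape + (0,))
        h = 1e-6
        out = np.empty(shape + (self.n_aux,))
        for j in range(self.n_aux):
            up = aux.copy()
            dn = aux.copy()
            up[j] += h
            dn[j] -= h
            out[..., j] = (self.loglik(y, eta, up) - self.loglik(y, eta, dn)) / (2 * h)
        return out

    def init_aux(self, y, mu):
        return np.zeros(self.n_aux)

    def init_eta(self, y):
        raise NotImplementedError

    def aux_bounds(self):
        return [(-12.0, 14.0)] * self.n_aux

    def validate(self, y):
        pass


class Poisson(Family):
    name = "poisson"

    def loglik(self, y, eta, aux):
        return y * eta - np.exp(eta) - gammaln(y + 1.0)

    def d1(self, y, eta, aux):
        return y - np.exp(eta)

    def d2(self, y, eta, aux):
        return -np.exp(eta)

    def init_eta(self, y):
        return np.log(y + 0.5)

    def validate(self, y):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson family requires non-negative integer response")


class NegativeBinomial(Family):
    """NB2: Var(y) = mu + alpha * mu^2; aux parameter is log(k) with k = 1/alpha."""

    name = "negative_binomial"
    n_aux = 1
    aux_names = ("log_size",)

    def loglik(self, y, eta, aux):
        k = np.exp(aux[0])
        mu = np.exp(eta)
        return (gammaln(y + k) - gammaln(k) - gammaln(y + 1.0)
                + k * np.log(k) - (y + k) * np.log(k + mu) + y * eta)

    def d1(self, y, eta, aux):
        k = np.exp(aux[0])
        mu = np.exp(eta)
        return (y - mu) * k / (k + mu)

    def d2(self, y, eta, aux):
        k = np.exp(aux[0])
        mu = np.exp(eta)
        return -(y + k) * k * mu / (k + mu) ** 2

    def d_aux(self, y, eta, aux):
        k = np.exp(aux[0])
        mu = np.exp(eta)
        g = k * (digamma(y + k) - digamma(k) + np.log(k) + 1.0
                 - np.log(k + mu) - (y + k) / (k + mu))
        return g[..., None]

    def init_aux(self, y, mu):
        resid = (y - mu) ** 2 - mu
        denom = np.maximum(mu, 1e-8) ** 2
        alpha = np.clip(np.mean(resid / denom), 0.02, 20.0)
        return np.array([np.log(1.0 / alpha)])

    def aux_bounds(self):
        return [(-8.0, 13.0)]

    def init_eta(self, y):
        return np.log(y + 0.5)

    def validate(self, y):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("negative_binomial family requires non-negative "
                             "integer response")


class Binomial(Family):
    name = "binomial_logit"

    def loglik(self, y, eta, aux):
        # yn - softplus(eta), stable for large |eta|
        return y * eta - np.logaddexp(0.0, eta)

    def d1(self, y, eta, aux):
        return y - expit(eta)

    def d2(self, y, eta, aux):
        p = expit(eta)
        return -p * (1.0 - p)

    def init_eta(self, y):
        p = np.clip(y, 0.02, 0.98)
        return np.log(p / (1 - p))

    def validate(self, y):
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("binomial family requires a 0/1 response")


class Beta(Family):
    """Logit-linked beta regression; aux is log precision phi."""

    name = "beta"
    n_aux = 1
    aux_names = ("log_precision",)

    def loglik(self, y, eta, aux):
        phi = np.exp(aux[0])
        mu = expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        return (gammaln(phi) - gammaln(a) - gammaln(b)
                + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))

    def d1(self, y, eta, aux):
        phi = np.exp(aux[0])
        mu = expit(eta)
        dmu = phi * (np.log(y) - np.log1p(-y)
                     - digamma(mu * phi) + digamma((1.0 - mu) * phi))
        return dmu * mu * (1.0 - mu)

    def d2(self, y, eta, aux):
        # negative expected information w.r.t. eta (Fisher scoring)
        phi = np.exp(aux[0])
        mu = expit(eta)
        info = phi ** 2 * (_trigamma(mu * phi) + _trigamma((1.0 - mu) * phi))
        return -info * (mu * (1.0 - mu)) ** 2

    def d_aux(self, y, eta, aux):
        phi = np.exp(aux[0])
        mu = expit(eta)
        g = phi * (digamma(phi) - mu * digamma(mu * phi)
                   - (1.0 - mu) * digamma((1.0 - mu) * phi)
                   + mu * np.log(y) + (1.0 - mu) * np.log1p(-y))
        return g[..., None]

    def init_aux(self, y, mu):
        v = max(np.var(y), 1e-4)
        m = np.mean(y)
        phi = np.clip(m * (1 - m) / v - 1.0, 0.5, 1e4)
        return np.array([np.log(phi)])

    def aux_bounds(self):
        return [(-5.0, 13.0)]

    def init_eta(self, y):
        p = np.clip(y, 0.02, 0.98)
        return np.log(p / (1 - p))

    def validate(self, y):
        if np.any(y <= 0) or np.any(y >= 1):
            raise ValueError("beta family requires responses strictly in (0, 1); "
                             "apply squeeze_proportions first")


class ProportionalOdds(Family):
    """Cumulative-logit (proportional odds) model for ordinal responses.

    The response must be integer codes 0..L-1.  The design matrix must not
    contain an intercept; the L-1 cutpoints play that role.  Aux parameters
    are (c_1, log(c_2-c_1), ..., log(c_{L-1}-c_{L-2})).
    """

    name = "proportional_odds"

    def __init__(self, n_levels: int):
        if n_levels < 3:
            raise ValueError("proportional odds model requires >= 3 levels")
        self.n_levels = int(n_levels)
        self.n_aux = self.n_levels - 1
        self.aux_names = tuple(
            ["cut_1"] + [f"log_step_{i}" for i in range(2, self.n_levels)])

    def _cuts(self, aux):
        c = np.empty(self.n_levels - 1)
        c[0] = aux[0]
        if self.n_levels > 2:
            c[1:] = aux[0] + np.cumsum(np.exp(aux[1:]))
        return c

    def _probs(self, y, eta, aux):
        c = self._cuts(aux)
        yi = y.astype(int)
        upper = np.where(yi >= self.n_levels - 1, np.inf, c[np.minimum(yi, self.n_levels - 2)] - eta)
        lower = np.where(yi <= 0, -np.inf, c[np.maximum(yi - 1, 0)] - eta)
        Fu = expit(upper)
        Fl = expit(lower)
        return Fu, Fl, upper, lower

    def loglik(self, y, eta, aux):
        Fu, Fl, _, _ = self._probs(y, eta, aux)
        return np.log(np.maximum(Fu - Fl, _LOG_EPS))

    def d1(self, y, eta, aux):
        Fu, Fl, _, _ = self._probs(y, eta, aux)
        fu = Fu * (1.0 - Fu)
        fl = Fl * (1.0 - Fl)
        return (fl - fu) / np.maximum(Fu - Fl, _LOG_EPS)

    def d2(self, y, eta, aux):
        Fu, Fl, _, _ = self._probs(y, eta, aux)
        fu = Fu * (1.0 - Fu)
        fl = Fl * (1.0 - Fl)
        P = np.maximum(Fu - Fl, _LOG_EPS)
        dfu = fu * (1.0 - 2.0 * Fu)
        dfl = fl * (1.0 - 2.0 * Fl)
        d1 = (fl - fu) / P
        return (dfu - dfl) / P - d1 ** 2

    def init_aux(self, y, mu):
        cum = np.array([np.mean(y <= l) for l in range(self.n_levels - 1)])
        cum = np.clip(cum, 0.02, 0.98)
        c = np.log(cum / (1 - cum))
        c = np.maximum.accumulate(c + np.arange(len(c)) * 1e-3)
        aux = np.empty(self.n_levels - 1)
        aux[0] = c[0]
        if self.n_levels > 2:
            aux[1:] = np.log(np.maximum(np.diff(c), 1e-3))
        return aux

    def aux_bounds(self):
        return [(None, None)] + [(-10.0, 10.0)] * (self.n_levels - 2)

    def init_eta(self, y):
        return np.zeros_like(np.asarray(y, dtype=float))

    def validate(self, y):
        if np.any(y != np.round(y)) or np.any(y < 0) or np.any(y > self.n_levels - 1):
            raise ValueError("ordinal response must be integer codes 0..L-1")


def get_family(name: str, **kwargs) -> Family:
    table = {
        "poisson": Poisson,
        "negative_binomial": NegativeBinomial,
        "binomial_logit": Binomial,
        "beta": Beta,
    }
    if name == "proportional_odds":
        return ProportionalOdds(kwargs["n_levels"])
    if name not in table:
        raise ValueError(f"unknown family: {name!r}")
    return table[name]()


def squeeze_proportions(y: np.ndarray) -> np.ndarray:
    """Pull proportions off the {0, 1} boundary: (y*(n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n
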