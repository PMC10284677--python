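import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, ndtri

from covdiff.glmm import (fit_random_intercept, normalize_continuous,
                          posthoc_pairwise)


class TestGaussian:
    def test_zero_between_individual_variance_collapses_to_ols(self, rng):
        """With sigma2_b = 0 in truth, the mixed fit equals plain OLS."""
        import statsmodels.api as sm
        n_ind, T = 40, 2
        ind = np.repeat(np.arange(n_ind), T)
        t = np.tile([1.0, 2.0], n_ind)
        X = np.column_stack([np.ones_like(t), t])
        y = 2.0 + 0.5 * t + rng.normal(0, 1, len(t))   # no individual effect
        fit = fit_random_intercept(y, X, ind, "gaussian_identity")
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.params, ols.params, atol=1e-6)


class TestNegativeBinomial:
    def test_low_dispersion_matches_poisson_family(self, rng):
        """NB with dispersion -> 0 (Poisson-like data) recovers the Poisson
        mixed-model coefficients."""
        n_ind, T = 75, 2
        ind = np.repeat(np.arange(n_ind), T)
        t = np.tile([1.0, 2.0], n_ind)
        b = rng.normal(0, 0.5, n_ind)
        mu = np.exp(3.0 + 0.6 * t + b[ind])
        y = rng.poisson(mu)
        X = np.column_stack([np.ones_like(t), t])
        nb = fit_random_intercept(y, X, ind, "negative_binomial")
        po = fit_random_intercept(y, X, ind, "poisson")
        assert nb.converged and po.converged
        assert np.all(np.abs(nb.params - po.params) < 0.05)

    def test_matches_glmmtmb_oracle(self, tmp_path, nb_longitudinal):
        """Independent oracle: R glmmTMB on the identical dataset."""
        d = nb_longitudinal
        df = pd.DataFrame({"y": d["y"], "t": d["t"], "ind": d["ind"]})
        path = tmp_path / "fix.csv"
        df.to_csv(path, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{path}")
            m <- glmmTMB(y ~ t + (1|ind), family=nbinom2, data=d)
            s <- summary(m)$coefficients$cond
            cat(s[,1], s[,2], VarCorr(m)$cond$ind[1], sigma(m), sep="\\n")
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        b0, bt, se0, set_, s2b, size = map(float, res.stdout.split())
        fit = fit_random_intercept(d["y"], d["X"], d["ind"],
                                   "negative_binomial",
                                   names=["const", "time"])
        assert fit.converged
        assert fit.params == pytest.approx([b0, bt], abs=2e-3)
        assert fit.bse == pytest.approx([se0, set_], rel=2e-2)
        assert fit.sigma2_b == pytest.approx(s2b, rel=0.05)
        assert np.exp(fit.dispersion["log_size"]) == pytest.approx(size,
                                                                   rel=0.05)

    def test_wald_interval_coverage(self):
        """95% Wald CI for beta_time covers the truth in >= 90 of 100
        seeded replicates (75 individuals x 2 time points)."""
        beta_t, k = 0.8, 2.0
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            n_ind = 75
            ind = np.repeat(np.arange(n_ind), 2)
            t = np.tile([1.0, 2.0], n_ind)
            b = rng.normal(0, np.sqrt(0.5), n_ind)
            mu = np.exp(2.0 + beta_t * t + b[ind])
            y = rng.negative_binomial(k, k / (k + mu))
            X = np.column_stack([np.ones_like(t), t])
            fit = fit_random_intercept(y, X, ind, "negative_binomial")
            if not fit.converged:
                continue
            lo = fit.params[1] - 1.96 * fit.bse[1]
            hi = fit.params[1] + 1.96 * fit.bse[1]
            hits += lo <= beta_t <= hi
        assert hits >= 90

    def test_quadrature_node_convergence(self, rng):
        """Laplace (1 node) and 5- and 25-node adaptive quadrature agree on
        the coefficients of a well-behaved fit."""
        n_ind, T = 80, 4
        ind = np.repeat(np.arange(n_ind), T)
        t = np.tile(np.arange(1.0, T + 1), n_ind)
        b = rng.normal(0, 0.3, n_ind)
        k = 50.0
        mu = np.exp(3.0 + 0.3 * t + b[ind])
        y = rng.negative_binomial(k, k / (k + mu))
        X = np.column_stack([np.ones_like(t), t])
        fits = [fit_random_intercept(y, X, ind, "negative_binomial",
                                     n_points=n) for n in (1, 5, 25)]
        for f in fits:
            assert f.converged
        assert np.all(np.abs(fits[0].params - fits[2].params) < 1e-3)
        assert np.all(np.abs(fits[1].params - fits[2].params) < 1e-3)

    def test_sample_order_invariance(self, nb_longitudinal, rng):
        d = nb_longitudinal
        fit1 = fit_random_intercept(d["y"], d["X"], d["ind"],
                                    "negative_binomial")
        perm = rng.permutation(len(d["y"]))
        fit2 = fit_random_intercept(d["y"][perm], d["X"][perm],
                                    d["ind"][perm], "negative_binomial")
        assert np.allclose(fit1.params, fit2.params, atol=1e-6)
        assert np.allclose(fit1.loglik, fit2.loglik, atol=1e-6)

    def test_nested_model_likelihood_ordering(self, nb_longitudinal):
        d = nb_longitudinal
        full = fit_random_intercept(d["y"], d["X"], d["ind"],
                                    "negative_binomial")
        null = fit_random_intercept(d["y"], d["X"][:, :1], d["ind"],
                                    "negative_binomial")
        assert full.loglik >= null.loglik - 1e-6


class TestOtherFamilies:
    def test_beta_recovery(self, rng):
        n_ind, T = 60, 2
        ind = np.repeat(np.arange(n_ind), T)
        t = np.tile([1.0, 2.0], n_ind)
        b = rng.normal(0, 0.4, n_ind)
        mu = expit(-1.0 + 0.5 * t + b[ind])
        phi = 30.0
        y = rng.beta(mu * phi, (1 - mu) * phi)
        X = np.column_stack([np.ones_like(t), t])
        fit = fit_random_intercept(y, X, ind, "beta")
        assert fit.converged
        assert abs(fit.params[1] - 0.5) < 3 * fit.bse[1]

    def test_binomial_recovery(self, rng):
        n_ind, T = 150, 2
        ind = np.repeat(np.arange(n_ind), T)
        t = np.tile([1.0, 2.0], n_ind)
        b = rng.normal(0, 0.5, n_ind)
        y = rng.binomial(1, expit(-1.0 + 0.8 * t + b[ind]))
        X = np.column_stack([np.ones_like(t), t])
        fit = fit_random_intercept(y, X, ind, "binomial_logit")
        assert fit.converged
        assert abs(fit.params[1] - 0.8) < 3 * fit.bse[1]

    def test_proportional_odds_recovery(self, rng):
        n_ind, T = 80, 3
        ind = np.repeat(np.arange(n_ind), T)
        t = np.tile(np.arange(1.0, T + 1), n_ind)
        b = rng.normal(0, 0.5, n_ind)
        eta = 0.7 * t + b[ind]
        u = rng.logistic(eta, 1.0)
        y = np.digitize(u, [1.0, 2.0, 3.0]).astype(float)
        fit = fit_random_intercept(y, t[:, None], ind, "proportional_odds",
                                   names=["time"], n_levels=4)
        assert fit.converged
        assert abs(fit.params[0] - 0.7) < 3 * fit.bse[0]


class TestDegenerateInputs:
    def test_constant_response_flagged(self, rng):
        t = np.tile([1.0, 2.0], 10)
        X = np.column_stack([np.ones_like(t), t])
        fit = fit_random_intercept(np.full(20, 3.0), X,
                                   np.repeat(np.arange(10), 2),
                                   "negative_binomial")
        assert not fit.converged
        assert fit.reason == "degenerate response"
        assert np.all(np.isnan(fit.pvalues))

    def test_rank_deficiency_flagged_not_dropped(self, rng):
        t = np.tile([1.0, 2.0], 20)
        X = np.column_stack([np.ones_like(t), t, t])   # exact collinearity
        y = rng.poisson(np.exp(1 + 0.2 * t))
        fit = fit_random_intercept(y, X, np.repeat(np.arange(20), 2),
                                   "negative_binomial")
        assert not fit.converged
        assert fit.reason == "rank_deficient"


class TestNormalizeContinuous:
    def test_blom_closed_form(self):
        v = np.array([10.0, 3.0, 7.0, 1.0, 5.0])
        r = pd.Series(v).rank().to_numpy()
        expected = ndtri((r - 3.0 / 8.0) / (5 + 0.25))
        assert np.allclose(normalize_continuous(v), expected)

    def test_monotone(self, rng):
        v = rng.normal(size=30)
        out = normalize_continuous(v)
        order = np.argsort(v)
        assert np.all(np.diff(out[order]) >= 0)

    def test_invariant_under_monotone_transform(self, rng):
        v = rng.uniform(1, 5, size=25)
        assert np.allclose(normalize_continuous(v),
                           normalize_continuous(np.exp(2 * v)))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize_continuous([2.0, 2.0, 2.0])


class TestPosthoc:
    def _fit_factor(self, rng, L=3, n_ind=50):
        ind = np.repeat(np.arange(n_ind), L)
        t = np.tile(np.arange(1.0, L + 1), n_ind)
        b = rng.normal(0, 0.5, n_ind)
        k = 10.0
        mu = np.exp(3.0 + 0.3 * t + b[ind])
        y = rng.negative_binomial(k, k / (k + mu))
        cols = [np.ones_like(t)] + [(t == lev).astype(float)
                                    for lev in range(2, L + 1)]
        X = np.column_stack(cols)
        slices = {"const": [0], "time": list(range(1, L))}
        fit = fit_random_intercept(
            y, X, ind, "negative_binomial",
            names=["const"] + [f"time[{v}]" for v in range(2, L + 1)],
            term_slices=slices)
        return fit, [float(v) for v in range(1, L + 1)]

    def test_two_levels_single_contrast_equals_wald(self, rng):
        fit, levels = self._fit_factor(rng, L=2)
        contrasts = posthoc_pairwise(fit, "time", levels)
        assert len(contrasts) == 1
        (_, est, p) = contrasts[0]
        assert p == pytest.approx(fit.pvalue("time[2]"), abs=1e-9)
        assert est == pytest.approx(fit.coef("time[2]"))

    def test_three_levels_three_contrasts(self, rng):
        fit, levels = self._fit_factor(rng, L=3)
        contrasts = posthoc_pairwise(fit, "time", levels)
        assert len(contrasts) == 3
        assert [c[0] for c in contrasts] == [(1.0, 2.0), (1.0, 3.0),
                                             (2.0, 3.0)]

    def test_contrast_antisymmetry_and_additivity(self, rng):
        fit, levels = self._fit_factor(rng, L=3)
        est = {pair: e for pair, e, _ in posthoc_pairwise(fit, "time", levels)}
        # (1,3) = (1,2) + (2,3); reversing a pair flips the sign by the
        # contrast-vector construction
        assert est[(1.0, 3.0)] == pytest.approx(
            est[(1.0, 2.0)] + est[(2.0, 3.0)])

    def test_nonconverged_fit_gives_empty_list(self):
        t = np.tile([1.0, 2.0], 10)
        X = np.column_stack([np.ones_like(t), (t == 2.0).astype(float)])
        fit = fit_random_intercept(np.full(20, 1.0), X,
                                   np.repeat(np.arange(10), 2),
                                   "negative_binomial",
                                   term_slices={"const": [0], "time": [1]})
        assert posthoc_pairwise(fit, "time", [1.0, 2.0]) == []
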