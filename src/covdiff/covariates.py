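"""Covariate screening, one-at-a-time model refits, and reducibility labels.

For every feature whose null time model is significant, candidate covariates
are screened with non-parametric tests, then each selected covariate is added
one at a time (never jointly) as a fixed effect next to the time variable.
The fate of the time term across these refits classifies the feature's time
effect as not reducible to any covariate, reducible to a covariate, or
entangled with one — the "vibration of effects" idea: a robust association
stays significant in every model configuration.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import build_design, prepare_response
from .glmm import fit_random_intercept, posthoc_pairwise
from .stats import kruskal_wallis, spearman_rho, wilcoxon_ranksum

logger = logging.getLogger(__name__)

# signal labels
NS = "NS"            # time not significant
OK_NC = "OK_nc"      # significant, no candidate covariates
OK_NRC = "OK_nrc"    # significant, not reducible to any covariate
RC = "RC"            # effect reducible to a covariate
EC = "EC"            # entangled with a covariate

NOT_REDUCIBLE = "NOT_REDUCIBLE"
REDUCIBLE = "REDUCIBLE"
ENTANGLED = "ENTANGLED"


@dataclass
class CovariateRecord:
    feature: str
    covariate: str
    screen_p: float
    model_time_p: float
    model_cov_p: float
    converged: bool = True
    status: str = ""


def screen_covariates(table, feature, alpha_screen=0.05, covariates=None):
    """Select covariates associated with the feature's values.

    Binary categorical covariates use the Wilcoxon rank-sum test, multi-level
    categorical ones Kruskal-Wallis, continuous ones Spearman correlation.
    Returns [(covariate, raw p)] for raw p < alpha_screen. ``covariates``
    restricts the candidate set (default: all of the table's covariates).
    """
    if not 0 < alpha_screen < 1:
        raise ValueError("alpha_screen must lie in (0, 1)")
    y_all = table.data[feature]
    selected = []
    candidates = table.covariate_cols if covariates is None else covariates
    for cov in candidates:
        v = table.data[cov]
        mask = v.notna() & y_all.notna()
        y = y_all[mask].to_numpy(dtype=float)
        vv = v[mask]
        n_levels = vv.nunique()
        if n_levels < 2:
            warnings.warn(f"covariate {cov!r} has a single observed level; "
                          "skipped")
            continue
        if table.covariate_type(cov) == "categorical":
            groups = [y[(vv == lev).to_numpy()] for lev in vv.unique()]
            if n_levels == 2:
                p = wilcoxon_ranksum(groups[0], groups[1])
            else:
                p = kruskal_wallis(groups)
        else:
            _, p = spearman_rho(vv.to_numpy(dtype=float), y)
        if np.isfinite(p) and p < alpha_screen:
            selected.append((cov, float(p)))
    return selected


def _joint_fit(table, feature, covariate, *, time_as_factor, test_var=None,
               n_points=10):
    """Fit feature ~ tested variable + covariate + (1|individual) on the
    covariate's complete cases."""
    rows = table.data[covariate].notna()
    X, names, slices, levels, idx = build_design(
        table, time_as_factor=time_as_factor, covariate=covariate, rows=rows,
        test_var=test_var)
    y, family, n_levels = prepare_response(
        table.data.loc[idx, feature], table.data_type)
    if family == "proportional_odds":
        X = X[:, 1:]
        names = names[1:]
        slices = {k: [i - 1 for i in v] for k, v in slices.items()}
    groups = table.data.loc[idx, table.individual_col]
    fit = fit_random_intercept(y, X, groups, family, names=names,
                               term_slices=slices, n_points=n_points,
                               n_levels=n_levels)
    return fit, levels


def _time_p_from_fit(fit, levels, time_as_factor):
    """Cont mode: Wald p of the time slope. Disc mode: the time term counts as
    significant when any post-hoc contrast is, so report the smallest
    pairwise-contrast p."""
    if not fit.converged:
        return np.nan
    if not time_as_factor:
        return fit.wald_term("time")
    contrasts = posthoc_pairwise(fit, "time", levels)
    ps = [p for _, _, p in contrasts if np.isfinite(p)]
    return min(ps) if ps else np.nan


def covariate_model_loop(table, feature, selected, *, time_as_factor=False,
                         test_var=None, n_points=10):
    """One joint GLMM per selected covariate (never all at once)."""
    records = []
    for cov, screen_p in selected:
        fit, levels = _joint_fit(table, feature, cov,
                                 time_as_factor=time_as_factor,
                                 test_var=test_var, n_points=n_points)
        if not fit.converged:
            logger.warning("joint model for feature %r / covariate %r did not "
                           "converge (%s)", feature, cov, fit.reason)
            records.append(CovariateRecord(feature, cov, screen_p,
                                           np.nan, np.nan, converged=False))
            continue
        time_p = _time_p_from_fit(fit, levels, time_as_factor)
        cov_p = fit.wald_term("covariate")
        records.append(CovariateRecord(feature, cov, screen_p,
                                       float(time_p), float(cov_p)))
    return records


def classify_feature(records, alpha_model=0.05):
    """Label a significant feature from its covariate-model records.

    Precedence: time significant in every converged model -> OK_nrc; else a
    model where time lost significance while the covariate kept it -> RC;
    otherwise -> EC. Non-converged records are excluded; with no records at
    all the label is OK_nc. Per-record statuses are filled in in place.
    """
    if not records:
        return OK_NC
    usable = [r for r in records if r.converged]
    if not usable:
        logger.warning("no interpretable covariate model; labeling EC")
        for r in records:
            r.status = ENTANGLED
        return EC
    for r in usable:
        time_sig = r.model_time_p < alpha_model
        cov_sig = r.model_cov_p < alpha_model
        if time_sig:
            r.status = NOT_REDUCIBLE
        elif cov_sig:
            r.status = REDUCIBLE
        else:
            r.status = ENTANGLED
    if all(r.status == NOT_REDUCIBLE for r in usable):
        return OK_NRC
    if any(r.status == REDUCIBLE for r in usable):
        return RC
    return EC


def vibration_summary(table, feature, selected, *, time_as_factor=False,
                      test_var=None, n_points=10):
    """Spread of the time effect across the null and all covariate models."""
    rows = []
    X, names, slices, levels, idx = build_design(
        table, time_as_factor=time_as_factor, test_var=test_var)
    y, family, n_levels = prepare_response(
        table.data.loc[idx, feature], table.data_type)
    if family == "proportional_odds":
        X, names = X[:, 1:], names[1:]
        slices = {k: [i - 1 for i in v] for k, v in slices.items()}
    groups = table.data.loc[idx, table.individual_col]
    null_fit = fit_random_intercept(y, X, groups, family, names=names,
                                    term_slices=slices, n_points=n_points,
                                    n_levels=n_levels)
    tcol = slices["time"][0]
    rows.append({"model": "null",
                 "time_beta": null_fit.params[tcol],
                 "time_p": _time_p_from_fit(null_fit, levels, time_as_factor)})
    for cov, _ in selected:
        fit, levels = _joint_fit(table, feature, cov,
                                 time_as_factor=time_as_factor,
                                 test_var=test_var, n_points=n_points)
        beta = fit.params[fit.term_slices["time"][0]] if fit.converged else np.nan
        rows.append({"model": f"time+{cov}", "time_beta": beta,
                     "time_p": _time_p_from_fit(fit, levels, time_as_factor)})
    df = pd.DataFrame(rows)
    df.attrs["beta_range"] = float(np.nanmax(df.time_beta)
                                   - np.nanmin(df.time_beta))
    df.attrs["p_range"] = float(np.nanmax(df.time_p) - np.nanmin(df.time_p))
    return df


def records_to_frame(records):
    return pd.DataFrame(
        [{"feature": r.feature, "covariate": r.covariate,
          "screen_p": r.screen_p, "model_time_p": r.model_time_p,
          "model_cov_p": r.model_cov_p, "status": r.status,
          "converged": r.converged}
         for r in records],
        columns=["feature", "covariate", "screen_p", "model_time_p",
                 "model_cov_p", "status", "converged"])


__all__ = ["CovariateRecord", "screen_covariates", "covariate_model_loop",
           "classify_feature", "vibration_summary", "records_to_frame",
           "NS", "OK_NC", "OK_NRC", "RC", "EC"]
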