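"""Design-matrix and response construction shared by the analysis drivers."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .glmm import normalize_continuous
from .families import squeeze_proportions


def prepare_response(values, data_type):
    """Map declared feature values to (y, family, n_levels) for model fitting."""
    v = np.asarray(values, dtype=float)
    if data_type == "count":
        return v, "negative_binomial", None
    if data_type == "proportion":
        return squeeze_proportions(v), "beta", None
    if data_type == "binary":
        return v, "binomial_logit", None
    if data_type == "ordinal":
        levels = np.sort(np.unique(v))
        codes = np.searchsorted(levels, v)
        if len(levels) < 3:
            # two observed ranks degrade gracefully to logistic regression
            return codes.astype(float), "binomial_logit", None
        return codes.astype(float), "proportional_odds", len(levels)
    if data_type == "continuous":
        return normalize_continuous(v), "gaussian_identity", None
    raise ValueError(f"unknown data_type {data_type!r}")


def build_design(table, *, time_as_factor, covariate=None, rows=None,
                 intercept=True, test_var=None):
    """Fixed-effects design for the tested variable (+ one optional covariate).

    ``test_var`` defaults to the table's time column. Discrete time is coded
    as an ordered factor with treatment contrasts against the first level.
    Categorical covariates are dummy-coded the same way. Returns
    (X, names, term_slices, time_levels, row_index); the tested variable's
    columns are registered under the term name "time" regardless of which
    column it is.
    """
    test_var = test_var or table.time_col
    df = table.data if rows is None else table.data.loc[rows]
    cols, names = [], []
    term_slices = {}
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("const")
    t = df[test_var].to_numpy(dtype=float)
    levels = None
    if time_as_factor:
        levels = np.sort(np.unique(table.data[test_var]))
        idx = []
        for lev in levels[1:]:
            cols.append((t == lev).astype(float))
            names.append(f"time[{lev:g}]")
            idx.append(len(names) - 1)
        term_slices["time"] = idx
    else:
        cols.append(t)
        names.append("time")
        term_slices["time"] = [len(names) - 1]
    if covariate is not None:
        if table.covariate_type(covariate) == "categorical":
            vals = df[covariate]
            clevels = pd.unique(vals.dropna())
            idx = []
            for lev in sorted(clevels, key=str)[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{covariate}[{lev}]")
                idx.append(len(names) - 1)
            term_slices["covariate"] = idx
        else:
            cols.append(df[covariate].to_numpy(dtype=float))
            names.append(covariate)
            term_slices["covariate"] = [len(names) - 1]
    X = np.column_stack(cols)
    return X, names, term_slices, levels, df.index


__all__ = ["prepare_response", "build_design"]
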