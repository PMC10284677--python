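"""User-facing analysis drivers: `run_disc`, `run_cont`, and the summary plot.

Per feature the driver fits a null random-intercept model of the tested
variable (time, by default), adjusts the per-feature p-values across features
(BH), runs post-hoc pairwise contrasts in disc mode, computes non-parametric
effect sizes, and routes significant features through the covariate screen /
one-covariate-at-a-time model loop to obtain a reducibility label.

Output is two tables: one row per feature (significance, effect sizes, label)
and one row per (significant feature, screened covariate) pair.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_tables import MasterTable
from .covariates import (NS, OK_NC, classify_feature, covariate_model_loop,
                         records_to_frame, screen_covariates)
from .design import build_design, prepare_response
from .glmm import fit_random_intercept, posthoc_pairwise
from .stats import bh_adjust, cliffs_delta, spearman_rho

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and options of one analysis run.

    q_null is the BH-adjusted significance cutoff of the null time model
    (default 0.1); q_posthoc the cutoff for post-hoc contrast q-values in
    disc mode (default 0.05). alpha_screen / alpha_model are the raw-p
    cutoffs of the covariate screen and of the within-model classification.
    """

    mode: str = "cont"
    data_type: str = "count"
    q_null: float = 0.1
    q_posthoc: float = 0.05
    alpha_screen: float = 0.05
    alpha_model: float = 0.05
    adjust: str = "bh"
    seed: int | None = None
    normalization: str | None = None
    n_quad_points: int = 10

    def __post_init__(self):
        for name in ("q_null", "q_posthoc", "alpha_screen", "alpha_model"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def _candidate_covariates(table: MasterTable, test_var: str):
    cands = [c for c in table.covariate_cols if c != test_var]
    if test_var != table.time_col:
        cands.append(table.time_col)
    return cands


def _null_fits(table, config, test_var, time_as_factor):
    X, names, slices, levels, idx = build_design(
        table, time_as_factor=time_as_factor, test_var=test_var)
    groups = table.data.loc[idx, table.individual_col]
    fits = {}
    for feat in table.feature_cols:
        y, family, n_levels = prepare_response(
            table.data.loc[idx, feat], table.data_type)
        Xf, nf, sf = X, names, slices
        if family == "proportional_odds":
            Xf, nf = X[:, 1:], names[1:]
            sf = {k: [i - 1 for i in v] for k, v in slices.items()}
        fits[feat] = fit_random_intercept(
            y, Xf, groups, family, names=nf, term_slices=sf,
            n_points=config.n_quad_points, n_levels=n_levels)
    return fits, levels


def _classify_significant(table, config, test_var, time_as_factor,
                          significant_feats):
    labels = {}
    all_records = []
    candidates = _candidate_covariates(table, test_var)
    for feat in significant_feats:
        if not candidates:
            labels[feat] = OK_NC
            continue
        selected = screen_covariates(table, feat, config.alpha_screen,
                                     covariates=candidates)
        if not selected:
            labels[feat] = OK_NC
            continue
        records = covariate_model_loop(
            table, feat, selected, time_as_factor=time_as_factor,
            test_var=test_var, n_points=config.n_quad_points)
        labels[feat] = classify_feature(records, config.alpha_model)
        all_records.extend(records)
    return labels, all_records


def run_cont(table: MasterTable, config: RunConfig | None = None,
             test_var: str | None = None):
    """Continuous-time analysis; returns (feature results, covariate records).

    ``test_var`` names the tested metadata column (default: the table's time
    column); when it differs from the time column, the true time variable
    joins the candidate covariates — the setup used to probe whether a
    suspected confounder carries signal beyond time.
    """
    config = config or RunConfig(mode="cont", data_type=table.data_type)
    test_var = test_var or table.time_col
    tvals = table.data[test_var].to_numpy(dtype=float)
    if len(np.unique(tvals)) < 2:
        raise ValueError(f"tested variable {test_var!r} must take >= 2 values")

    fits, _ = _null_fits(table, config, test_var, time_as_factor=False)
    feats = table.feature_cols
    raw_p = np.array([fits[f].wald_term("time") for f in feats], dtype=float)
    if np.all(np.isnan(raw_p)):
        warnings.warn("no feature model converged; returning empty result")
    q = bh_adjust(raw_p, method=config.adjust)

    effects = np.empty(len(feats))
    effect_p = np.empty(len(feats))
    for i, f in enumerate(feats):
        es, p = spearman_rho(tvals, table.data[f].to_numpy(dtype=float))
        effects[i] = es.value
        effect_p[i] = p
    # the post-hoc check of cont mode: the rank-correlation test of the
    # tested variable itself, BH-adjusted across features; a feature must
    # clear both the model q and this q to be called significant
    effect_q = bh_adjust(effect_p, method=config.adjust)
    significant = ((q < config.q_null) & ~np.isnan(q)
                   & (effect_q < config.q_posthoc) & ~np.isnan(effect_q))

    sig_feats = [f for f, s in zip(feats, significant) if s]
    labels, records = _classify_significant(table, config, test_var, False,
                                            sig_feats)
    results = pd.DataFrame({
        "feature": feats,
        "null_p": raw_p,
        "null_q": q,
        "significant": significant,
        "rho": effects,
        "rho_p": effect_p,
        "rho_q": effect_q,
        "label": [labels.get(f, NS) for f in feats],
    }).set_index("feature")
    results.attrs["effect_cols"] = ["rho"]
    results.attrs["mode"] = "cont"
    results.attrs["test_var"] = test_var
    return results, records_to_frame(records)


def _balanced_subtable(table: MasterTable):
    levels = table.time_levels()
    counts = table.data.groupby(table.individual_col)[table.time_col].nunique()
    keep = counts[counts == len(levels)].index
    dropped = counts.index.difference(keep).tolist()
    if dropped:
        msg = (f"dropping {len(dropped)} individual(s) not observed at every "
               f"time level: {dropped}")
        warnings.warn(msg)
        logger.warning(msg)
        data = table.data[table.data[table.individual_col].isin(keep)]
        table = MasterTable(data, table.individual_col, table.time_col,
                            table.feature_cols, table.data_type,
                            table.covariate_types)
    return table, levels


def run_disc(table: MasterTable, config: RunConfig | None = None,
             test_var: str | None = None):
    """Discrete-time analysis: time as an ordered factor with post-hoc
    pairwise contrasts and Cliff's delta effect sizes per interval."""
    config = config or RunConfig(mode="disc", data_type=table.data_type)
    if test_var is not None and test_var != table.time_col:
        raise ValueError("disc mode tests the table's own time column")
    test_var = table.time_col
    table, levels = _balanced_subtable(table)
    L = len(levels)
    if L < 2:
        raise ValueError("disc mode requires >= 2 time levels")

    fits, levels = _null_fits(table, config, test_var, time_as_factor=True)
    feats = table.feature_cols
    raw_p = np.array([fits[f].wald_term("time") for f in feats], dtype=float)
    if np.all(np.isnan(raw_p)):
        warnings.warn("no feature model converged; returning empty result")
    q = bh_adjust(raw_p, method=config.adjust)

    # post-hoc contrasts pooled into one BH family across features
    pairs = [(levels[a], levels[b]) for a in range(L) for b in range(a + 1, L)]
    ph_p = np.full((len(feats), len(pairs)), np.nan)
    for i, f in enumerate(feats):
        for (pair, est, p) in posthoc_pairwise(fits[f], "time", levels):
            ph_p[i, pairs.index(pair)] = p
    ph_q = bh_adjust(ph_p.ravel(), method=config.adjust).reshape(ph_p.shape)
    any_ph = np.nansum(ph_q < config.q_posthoc, axis=1) > 0
    significant = (q < config.q_null) & ~np.isnan(q) & any_ph

    # Cliff's delta per consecutive level pair plus (first, last)
    intervals = [(levels[i], levels[i + 1]) for i in range(L - 1)]
    if L > 2:
        intervals.append((levels[0], levels[-1]))
    tvals = table.data[table.time_col].to_numpy(dtype=float)
    delta = {}
    for (a, b) in intervals:
        col = f"delta_{a:g}_{b:g}"
        vals = np.empty(len(feats))
        for i, f in enumerate(feats):
            fv = table.data[f].to_numpy(dtype=float)
            vals[i] = cliffs_delta(fv[tvals == b], fv[tvals == a],
                                   interval=f"{a:g}->{b:g}").value
        delta[col] = vals
    delta_df = pd.DataFrame(delta, index=feats)
    cons = delta_df.iloc[:, :L - 1].to_numpy()
    flips = (np.nanmin(cons, axis=1) < -0.2) & (np.nanmax(cons, axis=1) > 0.2)
    for f in np.asarray(feats)[flips]:
        warnings.warn(f"feature {f!r}: consecutive-interval effect sizes "
                      "change sign (> 0.2); consider splitting the time range")

    sig_feats = [f for f, s in zip(feats, significant) if s]
    labels, records = _classify_significant(table, config, test_var, True,
                                            sig_feats)
    results = pd.DataFrame({
        "feature": feats,
        "null_p": raw_p,
        "null_q": q,
        "significant": significant,
        "label": [labels.get(f, NS) for f in feats],
    }).set_index("feature")
    for j, pair in enumerate(pairs):
        results[f"posthoc_p_{pair[0]:g}_{pair[1]:g}"] = ph_p[:, j]
        results[f"posthoc_q_{pair[0]:g}_{pair[1]:g}"] = ph_q[:, j]
    results = results.join(delta_df)
    results.attrs["effect_cols"] = list(delta_df.columns)
    results.attrs["posthoc_q_cols"] = [f"posthoc_q_{a:g}_{b:g}"
                                       for a, b in pairs]
    results.attrs["mode"] = "disc"
    results.attrs["test_var"] = test_var
    return results, records_to_frame(records)


def cuneiform_plot(results: pd.DataFrame, path, q_posthoc=0.05):
    """Summary plot: one row per significant feature, one marker per interval.

    Marker shape encodes the effect direction (up/down triangle), fill the
    magnitude, and a black outline marks intervals that are themselves
    significant; the right strip shows the covariate-status label.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "covdiff"
    if len(results) == 0:
        raise ValueError("empty result table")
    sig = results[results["significant"]]
    effect_cols = results.attrs.get(
        "effect_cols",
        [c for c in results.columns if c.startswith(("delta_", "rho"))
         and not c.endswith("_p")])
    ph_cols = results.attrs.get("posthoc_q_cols", [])
    if len(sig) == 0:
        fig, ax = plt.subplots(figsize=(4, 2))
        ax.text(0.5, 0.5, "no significant features", ha="center", va="center")
        ax.axis("off")
        fig.savefig(path, metadata={"Date": None})
        plt.close(fig)
        return path

    n, m = len(sig), len(effect_cols)
    fig, ax = plt.subplots(figsize=(1.2 * m + 4.5, 0.32 * n + 1.5))
    cmap = plt.get_cmap("coolwarm")
    for i, (feat, row) in enumerate(sig.iterrows()):
        for j, col in enumerate(effect_cols):
            v = row[col]
            if not np.isfinite(v):
                continue
            marker = "^" if v > 0 else ("v" if v < 0 else "o")
            if j < len(ph_cols):
                edge = "black" if row[ph_cols[j]] < q_posthoc else "lightgray"
            else:
                edge = "black" if row["significant"] else "lightgray"
            ax.scatter(j, i, marker=marker, s=140,
                       c=[cmap(0.5 + v / 2)], edgecolors=edge,
                       linewidths=1.2, zorder=3)
        ax.text(m + 0.35, i, str(row["label"]), va="center", fontsize=8)
    ax.set_yticks(range(n))
    ax.set_yticklabels(sig.index, fontsize=8)
    ax.set_xticks(range(m))
    ax.set_xticklabels(effect_cols, rotation=30, ha="right", fontsize=8)
    ax.set_xlim(-0.5, m + 1.6)
    ax.invert_yaxis()
    ax.set_title("effect sizes and covariate status")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path


__all__ = ["RunConfig", "run_cont", "run_disc", "cuneiform_plot"]
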