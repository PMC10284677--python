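"""Scoring of pipeline calls against simulation truth.

Metric conventions: FDR of a replicate with zero positive calls is 0 (which
makes "median FDR = 0" on null data well defined), TPR is missing when the
truth has no positives, and MCC is 0 when any confusion-matrix marginal is 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .covariates import EC, NS, RC
from .pipeline import RunConfig, run_cont
from .simulate import simulate

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


def confusion(calls: pd.Series, truth: pd.Series) -> ConfusionCounts:
    if set(calls.index) != set(truth.index):
        raise ValueError("calls and truth cover different feature sets")
    truth = truth.reindex(calls.index)
    c = calls.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(tp=int((c & t).sum()), fp=int((c & ~t).sum()),
                           tn=int((~c & ~t).sum()), fn=int((~c & t).sum()))


def score_calls(results: pd.DataFrame, truth_spiked: pd.Series) -> dict:
    """Accuracy, TPR, FDR and MCC of significant-vs-truth feature calls."""
    cc = confusion(results["significant"], truth_spiked)
    n = cc.total
    acc = (cc.tp + cc.tn) / n
    tpr = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) > 0 else np.nan
    fdr = cc.fp / (cc.tp + cc.fp) if (cc.tp + cc.fp) > 0 else 0.0
    marg = [cc.tp + cc.fp, cc.tp + cc.fn, cc.tn + cc.fp, cc.tn + cc.fn]
    if any(m == 0 for m in marg):
        mcc = 0.0
    else:
        mcc = ((cc.tp * cc.tn - cc.fp * cc.fn)
               / np.sqrt(float(marg[0]) * marg[1] * marg[2] * marg[3]))
    return {"tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn,
            "accuracy": acc, "tpr": tpr, "fdr": fdr, "mcc": float(mcc)}


@dataclass
class CovariateSuccess:
    """Outcome of one dummy-as-tested-variable run.

    ``success_rate`` is the fraction of truly spiked features whose verdict
    for the dummy is non-significant, reducible-to-covariate, or entangled
    (the per-feature rate whose failure share tracks the classification's
    alpha); ``all_correct`` is the stricter all-features indicator.
    """

    success_rate: float
    all_correct: bool
    verdicts: pd.Series
    results: pd.DataFrame


def covariate_success(dataset, config: RunConfig | None = None,
                      dummy: str | None = None) -> CovariateSuccess:
    """Did the pipeline correctly handle a time-correlated dummy variable?

    The dummy is run as the tested variable with the true time variable
    among the candidate covariates. A spiked feature's verdict for the dummy
    counts as correct when it is non-significant, reducible-to-covariate, or
    entangled — i.e. the dummy is never credited with an effect that time
    cannot explain.
    """
    dummies = dataset.truth_dummy[dataset.truth_dummy.astype(bool)].index
    if len(dummies) == 0:
        raise ValueError("dataset has no dummy covariate")
    dummy = dummy or dummies[0]
    results, _ = run_cont(dataset.table, config, test_var=dummy)
    spiked = dataset.truth_spiked[dataset.truth_spiked].index
    verdicts = results.loc[spiked, "label"]
    ok = verdicts.isin([NS, RC, EC])
    return CovariateSuccess(success_rate=float(ok.mean()),
                            all_correct=bool(ok.all()),
                            verdicts=verdicts, results=results)


def replicate_runner(configs, n_reps, seed, run_config: RunConfig | None = None):
    """Run simulate -> analyze -> score over a config grid; long-format table.

    One row per (config, replicate); failures are recorded with an ``error``
    column rather than dropped. Replicate seeds are spawned deterministically
    from ``seed``.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for ci, cfg in enumerate(configs):
        child = ss.spawn(1)[0]
        rep_seeds = child.generate_state(n_reps) % (2 ** 31)
        for r in range(n_reps):
            row = {"config": ci, "replicate": r, "seed": int(rep_seeds[r]),
                   "n_individuals": cfg.n_individuals,
                   "effect_rho_median": cfg.effect_rho_median,
                   "error": ""}
            try:
                ds = simulate(replace(cfg, seed=int(rep_seeds[r])))
                results, _ = run_cont(ds.table, run_config)
                row.update(score_calls(results, ds.truth_spiked))
            except Exception as exc:   # recorded, not silently dropped
                logger.warning("replicate (%d, %d) failed: %s", ci, r, exc)
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_metrics(metrics: pd.DataFrame, by=("config",)):
    """Median and quartiles of each metric per config."""
    cols = [c for c in ("accuracy", "tpr", "fdr", "mcc") if c in metrics]
    g = metrics.groupby(list(by))[cols]
    out = g.quantile([0.25, 0.5, 0.75]).unstack()
    return out


__all__ = ["ConfusionCounts", "confusion", "score_calls", "covariate_success",
           "replicate_runner", "summarize_metrics"]
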