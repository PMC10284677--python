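"""Longitudinal count-data simulator with known ground truth.

Latent feature trajectories are multivariate normal per individual with a
first-order autoregressive within-individual correlation structure
(Corr(y_s, y_t) = rho_AR^|s-t|). A fixed fraction of features is "spiked"
with a linear mean shift over time, calibrated so the median Spearman
correlation of spiked features with time hits a target. Latent values map to
counts by per-feature Poisson sampling around the exponentiated latent value
(a log-normal mean mixture, hence overdispersed counts), scaled so the
expected per-sample total matches the configured depth. Features are kept
independent on purpose: allocating reads compositionally would leak a
spurious time signal into every non-spiked feature as spiked features grow,
which the benchmark design (non-spiked features identically distributed at
every time point) excludes.

Negative-control constructors are provided: within-individual time shuffling
(destroys every real signal), dummy covariates correlated with time at a
target Spearman rho, and systematic depth bias between time points.
"""
from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_tables import MasterTable
from .normalization import rarefy

logger = logging.getLogger(__name__)

_CALIBRATION_SEED = 715_001  # fixed: calibration is a study condition, not RNG
_calibration_cache: dict = {}


@dataclass
class SimConfig:
    """Study-design parameters of one simulated dataset.

    ``effect_rho_median`` is the target median Spearman correlation between
    spiked feature counts and time (0 disables spiking); ``beta`` may pin the
    latent per-step mean shift directly, skipping calibration.
    """

    n_individuals: int = 75
    n_timepoints: int = 2
    n_features: int = 200
    n_spiked: int = 20
    effect_rho_median: float = 0.5
    rho_ar: float = 0.7
    n_dummy_covariates: int = 0
    dummy_rho: float = 0.5
    depth: int = 50_000
    seed: int = 0
    beta: float | None = None

    def validate(self):
        if self.n_spiked > self.n_features:
            raise ValueError("n_spiked must not exceed n_features")
        if not -1 < self.rho_ar < 1:
            raise ValueError("rho_ar must lie in (-1, 1)")
        if self.n_timepoints < 2:
            raise ValueError("need >= 2 time points")
        if self.effect_rho_median < 0 or self.effect_rho_median >= 1:
            raise ValueError("effect_rho_median must lie in [0, 1)")
        cap = _max_spearman(self.n_individuals, self.n_timepoints)
        if self.effect_rho_median > 0.95 * cap:
            raise ValueError(
                f"target rho {self.effect_rho_median} infeasible: a "
                f"continuous feature against {self.n_timepoints} tied time "
                f"levels at n={self.n_individuals} caps Spearman's rho at "
                f"~{cap:.3f}")


@dataclass
class SimDataset:
    """A master table plus the ground truth used to score pipeline calls."""

    table: MasterTable
    truth_spiked: pd.Series          # bool per feature
    truth_dummy: pd.Series           # bool per metadata column
    realized_effects: pd.Series      # Spearman rho vs time, spiked features
    realized_dummy_rho: dict = field(default_factory=dict)
    config: SimConfig | None = None


def _max_spearman(n_individuals, n_timepoints):
    """Spearman cap for a continuous variable vs tied, balanced time levels."""
    n = n_individuals * n_timepoints
    t = np.repeat(np.arange(n_timepoints), n_individuals)
    y = np.arange(n, dtype=float)
    return float(spearmanr(t, y).statistic)


def _ar1_chol(T, rho):
    idx = np.arange(T)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(cov)


def _simulate_counts(config: SimConfig, beta: float, rng):
    n, T, F = config.n_individuals, config.n_timepoints, config.n_features
    spiked = np.zeros(F, dtype=bool)
    spiked[:config.n_spiked] = True
    base = rng.normal(0.0, 1.0, F)                      # baseline abundances
    L = _ar1_chol(T, config.rho_ar)
    eps = rng.standard_normal((n, F, T)) @ L.T          # AR(1) within individual
    t_idx = np.arange(T, dtype=float)
    latent = base[None, :, None] + eps
    latent[:, spiked, :] += beta * t_idx[None, None, :]
    # per-feature Poisson counts around the exponentiated latent value, scaled
    # so the expected per-sample total is about `depth`; keeping features
    # independent preserves the design's promise that non-spiked features are
    # drawn from the same distribution at every time point
    scale = np.log(config.depth / F) - 0.5   # E[exp(N(0,1))] = e^0.5
    mu = np.exp(np.clip(latent + scale, None, 20.0))
    counts = rng.poisson(mu).transpose(0, 2, 1).astype(np.int64)
    return counts, spiked


def simulate(config: SimConfig) -> SimDataset:
    """Generate one dataset; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.beta is not None:
        beta = config.beta
    elif config.effect_rho_median == 0 or config.n_spiked == 0:
        beta = 0.0
    else:
        beta = calibrate_effect(config.effect_rho_median, config)
    counts, spiked = _simulate_counts(config, beta, rng)
    n, T, F = counts.shape[0], counts.shape[1], counts.shape[2]
    features = [f"feature_{j + 1}" for j in range(F)]
    sample_ids = [f"S{i + 1}_t{t + 1}" for i in range(n) for t in range(T)]
    flat = counts.reshape(n * T, F)
    data = pd.DataFrame(flat, index=pd.Index(sample_ids, name="sample_id"),
                        columns=features)
    data.insert(0, "individual", [f"I{i + 1}" for i in range(n)
                                  for _ in range(T)])
    data.insert(1, "time", [float(t + 1) for _ in range(n) for t in range(T)])
    table = MasterTable(data, "individual", "time", features, "count")
    tvals = data["time"].to_numpy()
    realized = pd.Series(
        {f: spearmanr(data[f].to_numpy(), tvals).statistic
         for f, s in zip(features, spiked) if s}, dtype=float)
    ds = SimDataset(
        table=table,
        truth_spiked=pd.Series(spiked, index=features),
        truth_dummy=pd.Series(dtype=bool),
        realized_effects=realized,
        config=config)
    if config.n_dummy_covariates > 0:
        ds = add_dummy_covariates(ds, config.n_dummy_covariates,
                                  config.dummy_rho,
                                  seed=rng.integers(2 ** 31))
    return ds


def calibrate_effect(target_rho_median, config: SimConfig,
                     pilot_reps=5, pilot_features=50, tol=0.02,
                     max_iter=50) -> float:
    """Latent mean shift whose realized spiked-feature rho median hits target.

    Monotone bisection over beta with common random numbers (the same pilot
    seeds at every beta), using small pilot datasets. Deterministic.
    """
    if not 0 < target_rho_median < 1:
        raise ValueError("target rho must lie in (0, 1)")
    key = (round(target_rho_median, 6), config.n_individuals,
           config.n_timepoints, config.n_features, config.n_spiked,
           round(config.rho_ar, 6), config.depth, pilot_reps, pilot_features)
    if key in _calibration_cache:
        return _calibration_cache[key]
    frac = config.n_spiked / config.n_features
    pilot = replace(config, n_features=pilot_features,
                    n_spiked=max(5, round(frac * pilot_features)),
                    n_dummy_covariates=0)

    def realized(beta):
        rhos = []
        for r in range(pilot_reps):
            rng = np.random.default_rng(_CALIBRATION_SEED + r)
            counts, spiked = _simulate_counts(pilot, beta, rng)
            n, T, _ = counts.shape
            t = np.tile(np.arange(T), n)
            flat = counts.reshape(n * T, -1)
            for j in np.flatnonzero(spiked):
                rhos.append(spearmanr(flat[:, j], t).statistic)
        return float(np.median(rhos))

    lo, hi = 0.0, 0.5
    it = 0
    while realized(hi) < target_rho_median:
        hi *= 2.0
        it += 1
        if hi > 32 or it > max_iter:
            raise RuntimeError(
                f"effect calibration failed to bracket target "
                f"{target_rho_median}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = realized(mid)
        if abs(r - target_rho_median) <= tol:
            _calibration_cache[key] = mid
            return mid
        if r < target_rho_median:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    logger.warning("calibration stopped at max_iter; realized %.3f", realized(mid))
    _calibration_cache[key] = mid
    return mid


def add_dummy_covariates(data: SimDataset, k, target_rho, seed) -> SimDataset:
    """Add k dummy metadata columns correlated with time at a target rho.

    Each dummy is a copy of the time column with a calibrated number of
    entries flipped to a different time level, chosen so the realized
    Spearman correlation with time is within +/-0.03 of the target. Keeping
    the dummies on the tied time levels is what lets very high targets
    (e.g. 0.99) be reached against a discrete time variable.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if target_rho >= 1:
        raise ValueError("target rho must be < 1")
    data = copy.deepcopy(data)
    table = data.table
    rng = np.random.default_rng(seed)
    tvals = table.data[table.time_col].to_numpy(dtype=float)
    levels = np.unique(tvals)
    n = len(tvals)
    for j in range(1, k + 1):
        order = rng.permutation(n)
        repl = np.array([rng.choice(levels[levels != tv]) for tv in tvals])
        best_m, best_err, best_rho = None, np.inf, None
        dummy = tvals.copy()
        rho = 1.0
        for m in range(n + 1):
            if m > 0:
                dummy[order[m - 1]] = repl[order[m - 1]]
                rho = spearmanr(dummy, tvals).statistic
            err = abs(rho - target_rho)
            if m >= 1 and err < best_err:
                best_m, best_err, best_rho = m, err, rho
            if rho < target_rho - 0.1:
                break
        if best_err > 0.03:
            raise ValueError(
                f"cannot reach dummy-time rho {target_rho} within 0.03 at "
                f"n={n}")
        dummy = tvals.copy()
        dummy[order[:best_m]] = repl[order[:best_m]]
        name = f"dummy{j}"
        table.data[name] = dummy
        data.truth_dummy.loc[name] = True
        data.realized_dummy_rho[name] = float(best_rho)
    return data


def shuffle_time_within_individual(data: SimDataset, seed) -> SimDataset:
    """Permute time labels independently within each individual.

    Features and covariates are untouched, so no genuine association with the
    (new) time variable remains; the ground truth is reset accordingly.
    """
    data = copy.deepcopy(data)
    table = data.table
    rng = np.random.default_rng(seed)
    df = table.data
    tcol = table.time_col
    for _, idx in df.groupby(table.individual_col, sort=False).groups.items():
        vals = df.loc[idx, tcol].to_numpy()
        df.loc[idx, tcol] = rng.permutation(vals)
    data.truth_spiked[:] = False
    data.realized_effects = pd.Series(dtype=float)
    return data


def apply_depth_bias(data: SimDataset, depth_t1, depth_t2, seed) -> SimDataset:
    """Rarefy first-time-point rows to depth_t1 and second to depth_t2.

    On null data this plants a systematic depth signal between time points
    and nothing else.
    """
    data = copy.deepcopy(data)
    table = data.table
    levels = table.time_levels()
    if len(levels) != 2:
        raise ValueError("depth bias is defined for two time points")
    df = table.data
    feats = table.feature_cols
    for lev, depth in zip(levels, (depth_t1, depth_t2)):
        mask = df[table.time_col] == lev
        block = df.loc[mask, feats]
        if (block.sum(axis=1) < depth).any():
            raise ValueError(f"depth {depth} exceeds a sample total at time "
                             f"{lev:g}")
        df.loc[mask, feats] = rarefy(block, depth, seed=seed).to_numpy()
    return data


__all__ = ["SimConfig", "SimDataset", "simulate", "calibrate_effect",
           "add_dummy_covariates", "shuffle_time_within_individual",
           "apply_depth_bias"]
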