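"""Count-matrix preprocessing: TSS, CSS, TMM, GMPR, CLR and rarefaction.

All functions take a samples x features matrix (DataFrame or ndarray) of
non-negative counts and return an object of the same kind. Scale-factor
methods (TMM, GMPR) return one factor per sample instead.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _as_array(counts):
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts
    return np.asarray(counts, dtype=float), None


def _wrap(values, template, like=None):
    if template is not None:
        return pd.DataFrame(values, index=template.index,
                            columns=template.columns)
    return values


def _sample_labels(template, n):
    if template is not None:
        return list(template.index)
    return list(range(n))


def tss(counts):
    """Total-sum scaling: divide each sample by its total count (row sum 1)."""
    x, template = _as_array(counts)
    depths = x.sum(axis=1)
    zero = np.flatnonzero(depths == 0)
    if len(zero):
        labels = [_sample_labels(template, len(x))[i] for i in zero]
        raise ValueError(f"all-zero sample(s): {labels}")
    return _wrap(x / depths[:, None], template)


CSS_RESCALE = 1000.0


def css(counts, quantile=0.5):
    """Cumulative-sum scaling at the given nonzero-count quantile.

    Each sample is divided by the sum of its counts at or below its q-th
    nonzero-count quantile, then multiplied by a fixed constant (1000) so the
    output stays on a count-like magnitude; a fixed constant keeps the result
    invariant to global rescaling of the input.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    x, template = _as_array(counts)
    n = len(x)
    factors = np.empty(n)
    labels = _sample_labels(template, n)
    for i in range(n):
        nz = x[i][x[i] > 0]
        if len(nz) < 2:
            warnings.warn(f"sample {labels[i]!r} has < 2 nonzero features; "
                          "using its total count (TSS-style) as scale")
            factors[i] = max(x[i].sum(), 1.0)
            continue
        q = np.quantile(nz, quantile)
        factors[i] = x[i][x[i] <= q].sum()
    return _wrap(x / factors[:, None] * CSS_RESCALE, template)


def _tmm_pair(obs, ref, logratio_trim, abs_trim):
    """Doubly trimmed, weighted mean of M-values for one sample vs reference."""
    n_o, n_r = obs.sum(), ref.sum()
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return np.nan
    o, r = obs[mask], ref[mask]
    m = np.log2((o / n_o) / (r / n_r))
    a = 0.5 * np.log2((o / n_o) * (r / n_r))
    w = 1.0 / ((n_o - o) / (n_o * o) + (n_r - r) / (n_r * r))
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    from scipy.stats import rankdata
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return f


def tmm(counts, ref_sample=None, logratio_trim=0.30, abs_trim=0.05):
    """Trimmed-mean-of-M-values scale factors (one per sample).

    The reference defaults to the sample whose TSS profile's 75th percentile
    is closest to the mean of those percentiles. The factor of the reference
    with itself is 1.
    """
    x, template = _as_array(counts)
    labels = _sample_labels(template, len(x))
    rel = x / x.sum(axis=1, keepdims=True)
    if ref_sample is None:
        p75 = np.quantile(rel, 0.75, axis=1)
        ref_idx = int(np.argmin(np.abs(p75 - p75.mean())))
    else:
        ref_idx = labels.index(ref_sample) if template is not None \
            else int(ref_sample)
    ref = x[ref_idx]
    factors = np.empty(len(x))
    for i in range(len(x)):
        f = _tmm_pair(x[i], ref, logratio_trim, abs_trim)
        if np.isnan(f):
            warnings.warn(f"sample {labels[i]!r} shares no nonzero feature "
                          "with the reference; factor set to 1")
            f = 0.0
        factors[i] = 2.0 ** f
    factors[ref_idx] = 1.0
    if template is not None:
        return pd.Series(factors, index=template.index)
    return factors


def gmpr(counts):
    """Geometric-mean-of-pairwise-ratios size factors (one per sample).

    r_jk is the median, over features nonzero in both samples j and k, of the
    count ratio; the size factor of j is the geometric mean of r_jk over all
    samples k (the self-ratio r_jj = 1 included, as in the reference
    implementation — this is what makes a 3x-scaled duplicate of a sample get
    a 3x factor in the two-sample case).
    """
    x, template = _as_array(counts)
    n = len(x)
    if n < 2:
        raise ValueError("GMPR requires >= 2 samples")
    labels = _sample_labels(template, n)
    logr = np.full((n, n), np.nan)
    for j in range(n):
        for k in range(j + 1, n):
            mask = (x[j] > 0) & (x[k] > 0)
            if not mask.any():
                continue
            med = np.median(np.log(x[j][mask]) - np.log(x[k][mask]))
            logr[j, k] = med
            logr[k, j] = -med
    factors = np.empty(n)
    for j in range(n):
        vals = logr[j][~np.isnan(logr[j])]
        if len(vals) == 0:
            raise ValueError(f"sample {labels[j]!r} shares no nonzero feature "
                             "with any other sample")
        factors[j] = np.exp(np.sum(vals) / (len(vals) + 1))  # + self-ratio 1
    if template is not None:
        return pd.Series(factors, index=template.index)
    return factors


def clr(counts, pseudocount=None):
    """Centered log-ratio transform; rows sum to zero.

    The default pseudocount is half the smallest nonzero value in the matrix.
    """
    x, template = _as_array(counts)
    if pseudocount is None:
        nz = x[x > 0]
        if len(nz) == 0:
            raise ValueError("matrix is all zero")
        pseudocount = 0.5 * nz.min()
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logx = np.log(x + pseudocount)
    out = logx - logx.mean(axis=1, keepdims=True)
    return _wrap(out, template)


def rarefy(counts, depth, seed=None):
    """Randomly subsample each sample, without replacement, to a common depth.

    Samples whose total is below ``depth`` are dropped with a warning. The
    draw per sample is multivariate hypergeometric, so every retained output
    row sums exactly to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    depth = int(depth)
    x, template = _as_array(counts)
    xi = np.asarray(np.round(x), dtype=np.int64)
    totals = xi.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = [_sample_labels(template, len(x))[i]
                   for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping sample(s) below depth {depth}: {dropped}")
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), x.shape[1]), dtype=np.int64)
    for row, i in enumerate(np.flatnonzero(keep)):
        if totals[i] == depth:
            out[row] = xi[i]
        else:
            out[row] = rng.multivariate_hypergeometric(xi[i], depth,
                                                       method="marginals")
    if template is not None:
        return pd.DataFrame(out, index=template.index[keep],
                            columns=template.columns)
    return out


__all__ = ["tss", "css", "tmm", "gmpr", "clr", "rarefy"]
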