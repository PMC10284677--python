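import numpy as np
import pandas as pd
import pytest

from covdiff.core_tables import MasterTable


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def toy_master():
    """6 individuals x 2 time points, 3 count features.

    feature_a separates completely between time points (after > before for
    every pair); feature_b is pure noise; feature_c is constant.
    """
    n = 6
    rows = []
    for i in range(n):
        rows.append({"sample": f"s{i}a", "individual": f"I{i}", "time": 1.0,
                     "feature_a": 10 + i, "feature_b": [7, 3, 9, 2, 8, 5][i],
                     "feature_c": 4})
        rows.append({"sample": f"s{i}b", "individual": f"I{i}", "time": 2.0,
                     "feature_a": 30 + i, "feature_b": [4, 8, 2, 9, 3, 6][i],
                     "feature_c": 4})
    df = pd.DataFrame(rows).set_index("sample")
    return MasterTable(df, "individual", "time",
                       ["feature_a", "feature_b", "feature_c"], "count")


@pytest.fixture
def nb_longitudinal(rng):
    """Negative-binomial counts from a known random-intercept model."""
    n_ind, T = 60, 2
    ind = np.repeat(np.arange(n_ind), T)
    t = np.tile(np.arange(1.0, T + 1), n_ind)
    b = rng.normal(0, 0.7, n_ind)
    k = 8.0
    mu = np.exp(4.0 + 0.5 * t + b[ind])
    y = rng.negative_binomial(k, k / (k + mu))
    X = np.column_stack([np.ones_like(t), t])
    return {"y": y, "X": X, "ind": ind, "t": t,
            "truth": {"beta0": 4.0, "beta_time": 0.5, "sigma2_b": 0.49,
                      "size": k}}
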