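import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from covdiff.normalization import clr, css, gmpr, rarefy, tmm, tss


@pytest.fixture
def counts(rng):
    c = rng.negative_binomial(3, 0.02, size=(5, 10)).astype(np.int64)
    c[c < 0] = 0
    return pd.DataFrame(c, index=[f"s{i}" for i in range(5)],
                        columns=[f"f{j}" for j in range(10)])


class TestTSS:
    def test_definition(self):
        out = tss(np.array([[2, 3, 5]]))
        assert np.allclose(out, [[0.2, 0.3, 0.5]])

    def test_single_feature(self):
        assert np.allclose(tss(np.array([[7]])), [[1.0]])

    def test_scale_invariance(self, counts):
        doubled = counts * 13
        pd.testing.assert_frame_equal(tss(counts), tss(doubled))

    def test_rows_sum_to_one(self, counts):
        assert np.allclose(tss(counts).sum(axis=1), 1.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            tss(pd.DataFrame([[1, 2], [0, 0]], index=["s0", "s1"]))


class TestCSS:
    def test_identical_samples_identical_rows(self):
        row = [5, 0, 12, 3, 40, 7]
        out = css(np.array([row, row, [1, 2, 3, 4, 5, 6]]))
        assert np.allclose(out[0], out[1])

    def test_global_doubling_invariant(self):
        x = np.array([[5, 0, 12, 3], [1, 9, 2, 30], [4, 4, 4, 4]])
        # doubling every count doubles every cumulative sum and the global
        # median, so the normalized matrix is unchanged
        assert np.allclose(css(x), css(2 * x))

    def test_quantile_out_of_range(self, counts):
        with pytest.raises(ValueError):
            css(counts, quantile=1.0)

    def test_sparse_sample_falls_back_with_warning(self):
        x = np.array([[10, 20, 30, 40], [0, 0, 0, 7]])
        with pytest.warns(UserWarning, match="nonzero"):
            out = css(x)
        assert np.all(np.isfinite(out))


class TestTMM:
    def test_identical_to_reference_is_one(self):
        x = np.tile([10, 20, 30, 40, 50], (3, 1))
        f = tmm(x)
        assert np.allclose(f, 1.0)

    def test_untrimmed_equals_weighted_mean(self, rng):
        x = rng.poisson(50, size=(2, 30)) + 1
        f = tmm(x, ref_sample=0, logratio_trim=0.0, abs_trim=0.0)
        o, r = x[1].astype(float), x[0].astype(float)
        no, nr = o.sum(), r.sum()
        m = np.log2((o / no) / (r / nr))
        w = 1.0 / ((no - o) / (no * o) + (nr - r) / (nr * r))
        assert np.isclose(np.log2(f[1]), np.sum(w * m) / np.sum(w))

    def test_feature_order_invariance(self, counts, rng):
        f1 = tmm(counts)
        perm = rng.permutation(counts.shape[1])
        f2 = tmm(counts.iloc[:, perm])
        assert np.allclose(f1.to_numpy(), f2.to_numpy())

    def test_matches_edger(self, tmp_path, counts):
        """Independent oracle: edgeR's calcNormFactors on the same matrix."""
        mat = tmp_path / "counts.tsv"
        counts.T.to_csv(mat, sep="\t")      # edgeR wants features x samples
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{mat}", row.names=1))
            cat(calcNormFactors(x, method="TMM"), sep="\\n")
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        oracle = np.array([float(v) for v in res.stdout.split()])
        ours = tmm(counts).to_numpy()
        ours = ours / np.exp(np.mean(np.log(ours)))   # edgeR geomean-normalizes
        assert np.allclose(ours, oracle, rtol=1e-4)


class TestGMPR:
    def test_identical_samples(self):
        x = np.tile([3, 6, 9, 1], (4, 1))
        assert np.allclose(gmpr(x), 1.0)

    def test_threefold_sample(self):
        x = np.array([[2, 4, 8, 10], [6, 12, 24, 30]])
        f = gmpr(x)
        assert np.isclose(f[1] / f[0], 3.0)

    def test_permutation_equivariance(self, counts, rng):
        f1 = gmpr(counts).to_numpy()
        perm = rng.permutation(len(counts))
        f2 = gmpr(counts.iloc[perm]).to_numpy()
        assert np.allclose(f1[perm], f2)

    def test_scale_equivariance(self, counts):
        # scaling sample j by c scales every off-diagonal ratio r_jk by c;
        # with the self-ratio in the geometric mean the factor scales by
        # c^((n-1)/n)
        scaled = counts.copy()
        scaled.iloc[2] *= 5
        f1 = gmpr(counts).to_numpy()
        f2 = gmpr(scaled).to_numpy()
        n = len(counts)
        assert np.isclose(f2[2] / f1[2], 5.0 ** ((n - 1) / n))

    def test_matches_pairwise_median_definition(self, counts):
        x = counts.to_numpy(dtype=float)
        f = gmpr(counts).to_numpy()
        for j in range(len(x)):
            logs = []
            for k in range(len(x)):
                if k == j:
                    continue
                mask = (x[j] > 0) & (x[k] > 0)
                if mask.any():
                    logs.append(np.median(np.log(x[j][mask] / x[k][mask])))
            logs.append(0.0)   # self-ratio
            assert np.isclose(f[j], np.exp(np.mean(logs)))

    def test_disjoint_sample_rejected(self):
        x = np.array([[1, 1, 0, 0], [2, 3, 0, 0], [0, 0, 5, 9]])
        with pytest.raises(ValueError, match="2"):
            gmpr(x)


class TestCLR:
    def test_constant_row_is_zero(self):
        out = clr(np.array([[1, 1, 1, 1]]), pseudocount=1e-12)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_closed_form_two_features(self):
        out = clr(np.array([[1, 4]]), pseudocount=1e-9)
        assert np.allclose(out, [[-np.log(2), np.log(2)]], atol=1e-6)

    def test_rows_sum_to_zero(self, counts):
        assert np.allclose(clr(counts).sum(axis=1), 0.0, atol=1e-9)

    def test_default_pseudocount_is_half_min_nonzero(self):
        x = np.array([[0, 4], [8, 2]])
        expected = clr(x, pseudocount=1.0)
        assert np.allclose(clr(x).to_numpy() if hasattr(clr(x), "to_numpy")
                           else clr(x), expected)


class TestRarefy:
    def test_exact_depth_unchanged(self):
        x = np.array([[3, 4, 3], [10, 0, 10]])
        out = rarefy(x, 10, seed=0)
        assert np.array_equal(out[0], [3, 4, 3])

    def test_determinism(self, counts):
        d = int(counts.sum(axis=1).min())
        a = rarefy(counts, d, seed=42)
        b = rarefy(counts, d, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_row_sums_equal_depth(self, counts):
        d = int(counts.sum(axis=1).min()) // 2
        out = rarefy(counts, d, seed=1)
        assert (out.sum(axis=1) == d).all()

    def test_hypergeometric_expectation(self):
        # E[rarefied count] = depth * proportion; mean over seeded draws
        row = np.array([[300, 500, 200]])
        depth = 100
        draws = np.array([rarefy(row, depth, seed=s)[0, 0]
                          for s in range(1000)])
        expect = depth * 0.3
        se = np.sqrt(depth * 0.3 * 0.7 * (1000 - depth) / (1000 - 1)) / np.sqrt(1000)
        assert abs(draws.mean() - expect) < 3 * se

    def test_shallow_samples_dropped_with_warning(self):
        x = pd.DataFrame([[5, 5], [1, 1]], index=["deep", "shallow"])
        with pytest.warns(UserWarning, match="shallow"):
            out = rarefy(x, 4, seed=0)
        assert list(out.index) == ["deep"]

    def test_nonpositive_depth_rejected(self, counts):
        with pytest.raises(ValueError):
            rarefy(counts, 0)
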