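"""Group statistics: t-tests, BH-FDR, and Tukey-biweight regression."""

import numpy as np
import pandas as pd
import pytest

import rovingdcm as rd


def brute_force_bh(p, q):
    """Independent step-up oracle for Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        adj[idx] = running
    return adj, adj < q


def irls_tukey_oracle(x, y, c=4.685, tol=1e-12, maxiter=1000):
    """Independently coded IRLS with MAD scale recomputed per iteration.

    The MAD is divided by the normal consistency constant Phi^-1(3/4)."""
    from scipy.stats import norm

    mad_const = norm.ppf(0.75)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    w = np.ones_like(y)
    for _ in range(maxiter):
        r = y - X @ beta
        scale = np.median(np.abs(r)) / mad_const
        if scale == 0:
            break
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        W = X.T * w
        beta_new = np.linalg.solve(W @ X, W @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta, w


class TestTTests:
    def test_matches_textbook_formula(self):
        values = np.array([2.1, -0.3, 1.7, 0.4, 0.9])
        res = rd.one_sample_t(values, null_mean=0.5)
        n = 5
        mean = values.mean()
        sd = np.sqrt(((values - mean) ** 2).sum() / (n - 1))
        assert res.t == pytest.approx((mean - 0.5) / (sd / np.sqrt(n)), abs=1e-12)
        assert res.df == 4
        assert 0 < res.p < 1

    def test_null_sample(self):
        values = np.array([1.0, 3.0, 2.0])
        res = rd.one_sample_t(values, null_mean=2.0)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_degenerate_sample(self):
        with pytest.raises(ValueError):
            rd.one_sample_t(np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            rd.one_sample_t(np.array([1.0]))

    def test_summary_t(self):
        assert rd.summary_t(-1.5, 17.5, 30) == pytest.approx(-0.4695, abs=1e-3)
        assert rd.summary_t(0.0, 5.0, 12) == 0.0
        with pytest.raises(ValueError):
            rd.summary_t(1.0, 0.0, 10)


class TestBHFDR:
    def test_single_p(self):
        adj, flags = rd.bh_fdr(np.array([0.03]), q=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert flags[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.beta(0.4, 3.0, size=25)
        adj, flags = rd.bh_fdr(p, q=0.05)
        adj_o, flags_o = brute_force_bh(p, 0.05)
        assert np.allclose(adj, adj_o)
        assert np.array_equal(flags, flags_o)

    def test_known_values(self):
        p = np.array([0.001, 0.01, 0.02, 0.03, 0.04])
        adj, _ = rd.bh_fdr(p, q=0.05)
        assert np.allclose(adj, [0.005, 0.025, 1 / 30, 0.0375, 0.04])

    def test_ties_and_bounds(self):
        adj, _ = rd.bh_fdr(np.array([0.2, 0.2, 0.2]))
        assert np.allclose(adj, 0.2)
        with pytest.raises(ValueError):
            rd.bh_fdr(np.array([0.5, 1.5]))

    def test_adjusted_at_least_raw_and_flags_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.random(40)
        adj, flags = rd.bh_fdr(p, q=0.1)
        assert np.all(adj >= p - 1e-15)
        # flags respect the p-value ordering
        order = np.argsort(p)
        f = flags[order]
        assert not np.any(f[1:] & ~f[:-1])

    def test_weak_fdr_control_under_null(self):
        """With 25 true-null t-tests per replicate, the chance of any FDR
        flag stays near the nominal level q."""
        q = 0.05
        n_rep, m, n = 1000, 25, 25
        rng = np.random.default_rng(2024)
        false_any = 0
        for _ in range(n_rep):
            data = rng.normal(size=(n, m))
            p = np.array([rd.one_sample_t(data[:, j]).p for j in range(m)])
            _, flags = rd.bh_fdr(p, q)
            false_any += flags.any()
        rate = false_any / n_rep
        se = np.sqrt(q * (1 - q) / n_rep)
        assert rate <= q + 3 * se


class TestTukeyRegression:
    def test_collinear_data_equals_least_squares(self):
        x = np.linspace(0, 1, 15)
        y = 2.0 + 3.0 * x
        res = rd.tukey_regression(x, y)
        assert res.slope == pytest.approx(3.0, abs=1e-6)
        assert res.intercept == pytest.approx(2.0, abs=1e-6)
        assert np.all(res.weights >= 0.99)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_irls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = 1.5 - 2.0 * x + rng.normal(0, 0.5, 30)
        y[seed] += 12.0  # one gross outlier
        res = rd.tukey_regression(x, y)
        (b0, b1), w = irls_tukey_oracle(x, y)
        assert res.slope == pytest.approx(b1, abs=1e-6)
        assert res.intercept == pytest.approx(b0, abs=1e-6)
        assert res.weights[seed] == pytest.approx(w[seed], abs=1e-6)
        assert res.weights[seed] == 0.0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            rd.tukey_regression(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            rd.tukey_regression(np.arange(2.0), np.arange(2.0))

    def test_r_squared_tracks_noise(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        clean = rd.tukey_regression(x, 1.0 + 2.0 * x + rng.normal(0, 0.01, 200))
        noisy = rd.tukey_regression(x, 1.0 + 2.0 * x + rng.normal(0, 5.0, 200))
        assert clean.r_squared > 0.99
        assert noisy.r_squared < clean.r_squared


class TestGroupAnalysis:
    @pytest.fixture
    def tables(self):
        spec = rd.NetworkSpec.full_model()
        packer = rd.ParameterPacker(spec)
        b_names = [nm for nm in packer.names if nm.startswith("B1")]
        rng = np.random.default_rng(5)
        idx = [f"sub-{i:02d}" for i in range(25)]
        params = pd.DataFrame(rng.normal(0.1, 0.1, size=(25, len(b_names))),
                              columns=b_names, index=idx)
        ratings = pd.DataFrame(
            {"difficulty": rng.uniform(10, 60, 25),
             "intensity_difference": rng.normal(11, 19, 25)}, index=idx)
        return params, ratings

    def test_battery_shape(self, tables):
        params, ratings = tables
        out = rd.run_group_analysis(params, ratings, q=0.05)
        assert len(out.ttests) == 25
        assert len(out.difficulty_regressions) == 20
        assert len(out.control_regressions) == 20
        assert np.all(out.ttests["p_fdr"] >= out.ttests["p"] - 1e-15)

    def test_row_order_invariance(self, tables):
        params, ratings = tables
        a = rd.run_group_analysis(params, ratings)
        perm = np.random.default_rng(0).permutation(len(params))
        b = rd.run_group_analysis(params.iloc[perm], ratings.iloc[perm])
        assert np.allclose(a.ttests["t"], b.ttests["t"])
        assert np.allclose(a.difficulty_regressions["slope"],
                           b.difficulty_regressions["slope"])

    def test_subject_mismatch(self, tables):
        params, ratings = tables
        with pytest.raises(ValueError):
            rd.run_group_analysis(params.iloc[:20], ratings)
        with pytest.raises(ValueError):
            rd.run_group_analysis(params.iloc[:1], ratings.iloc[:1])
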