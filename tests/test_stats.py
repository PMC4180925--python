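import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from homecage.simulate import PAPER_STRAIN_N, simulate_strain_values
from homecage.stats import (
    anova_bonferroni,
    effectsize_by_category,
    heritability,
    maybe_log10,
    pca_kaiser,
    shared_genetic_variance,
    varimax,
    winsorize_5sd,
)


class TestTransform:
    def test_lognormal_sample_is_transformed(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(0, 1, 500)
        out, applied = maybe_log10(v)
        assert applied
        assert sps.skew(out, bias=False) < sps.skew(v, bias=False)

    def test_symmetric_sample_untouched(self):
        # exactly symmetric positive sample: skew 0, not positive
        rng = np.random.default_rng(1)
        half = rng.normal(10, 1, 250)
        v = np.concatenate([half, 20.0 - half])
        out, applied = maybe_log10(v)
        assert not applied
        np.testing.assert_array_equal(out, v)

    def test_zero_containing_sample_untouched(self):
        v = np.array([0.0, 1.0, 2.0, 50.0, 3.0])
        _out, applied = maybe_log10(v)
        assert not applied


class TestWinsorize:
    def test_inliers_unchanged(self):
        v = np.arange(20.0)
        out, n = winsorize_5sd(v)
        assert n == 0
        np.testing.assert_array_equal(out, v)

    def test_single_outlier_set_to_exact_limit(self):
        v = np.concatenate([np.zeros(50), np.ones(50), [1000.0]])
        out, n = winsorize_5sd(v)
        assert n == 1
        limit = v.mean() + 5 * v.std(ddof=1)
        assert out[-1] == pytest.approx(limit)

    def test_changes_only_tails_and_is_monotone(self):
        """Winsorizing touches only the points beyond the limits and is a
        monotone map, so the rank order of untouched points is intact."""
        rng = np.random.default_rng(2)
        v = rng.standard_t(2, size=300) * 10
        w, n = winsorize_5sd(v)
        changed = np.flatnonzero(w != v)
        assert len(changed) == n > 0
        lo, hi = w.min(), w.max()
        assert set(np.unique(w[changed])) <= {lo, hi}
        order = np.argsort(v, kind="stable")
        assert (np.diff(w[order]) >= 0).all()

    def test_rewinsorizing_touches_only_already_clipped_points(self):
        """Limits recomputed from the clipped sample can only tighten, so a
        second pass may nudge the already-clipped tails but never a point
        that was inside the limits."""
        v = np.concatenate([np.linspace(-3, 3, 200), [25.0]])
        w1, n1 = winsorize_5sd(v)
        w2, _ = winsorize_5sd(w1)
        assert n1 == 1
        moved = np.flatnonzero(w2 != w1)
        first_clipped = np.flatnonzero(w1 != v)
        assert set(moved) <= set(first_clipped)

    def test_constant_input_unchanged(self):
        out, n = winsorize_5sd(np.full(10, 3.0))
        assert n == 0


class TestHeritability:
    def test_hand_computed_balanced_toy(self):
        """3 strains x 4 animals, integer data; variance components done by
        hand: MSb=64, MSw=2/3, n0=4, Vb=15.8333, Vw=2/3 ->
        h2 = 7.91667/8.58333 = 0.92233."""
        vals = np.array([1, 2, 3, 2,  5, 6, 7, 6,  9, 10, 11, 10], float)
        labels = np.repeat(["A", "B", "C"], 4)
        h2, vc = heritability(vals, labels)
        assert vc.ms_between == pytest.approx(64.0)
        assert vc.ms_within == pytest.approx(2.0 / 3.0)
        assert vc.n0 == pytest.approx(4.0)
        assert vc.v_between == pytest.approx((64 - 2 / 3) / 4)
        assert h2 == pytest.approx(0.92233, abs=1e-5)

    def test_unequal_n_effective_size(self):
        """n0 = (N - sum(n_i^2)/N) / (a-1) for groups of 2, 3, 5."""
        rng = np.random.default_rng(3)
        vals = rng.normal(size=10)
        labels = np.repeat(["a", "b", "c"], [2, 3, 5])
        _h2, vc = heritability(vals, labels)
        assert vc.n0 == pytest.approx((10 - 38 / 10) / 2)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        vals, labels = simulate_strain_values(PAPER_STRAIN_N, 0.4, seed=5)
        h1, _ = heritability(vals, labels)
        h2, _ = heritability(3.7 * vals - 11.0, labels)
        assert h1 == pytest.approx(h2, rel=1e-10)

    def test_all_identical_values_give_zero(self):
        vals = np.ones(20)
        labels = np.repeat(["a", "b"], 10)
        h2, _ = heritability(vals, labels)
        assert h2 == 0.0

    def test_no_strain_effect_limit(self):
        """Null data at large n: the floored between-component pushes h2
        towards zero."""
        ests = [heritability(*simulate_strain_values(PAPER_STRAIN_N, 0.0, seed=k))[0]
                for k in range(50)]
        assert np.mean(ests) < 0.05


class TestAnovaBonferroni:
    def _matrix(self, n_params, seed=0):
        rng = np.random.default_rng(seed)
        vals, labels = simulate_strain_values(PAPER_STRAIN_N, 0.3, seed=seed)
        df = pd.DataFrame(
            rng.normal(size=(len(vals), n_params)),
            index=[f"m{i}" for i in range(len(vals))])
        df.iloc[:, 0] = vals
        return df, pd.Series(labels, index=df.index)

    def test_threshold_with_115_parameters(self):
        df, labels = self._matrix(115)
        res = anova_bonferroni(df, labels)
        assert res.attrs["threshold"] == pytest.approx(4.3478e-4, rel=1e-3)

    def test_single_parameter_threshold_is_alpha(self):
        df, labels = self._matrix(1)
        res = anova_bonferroni(df, labels)
        assert res.attrs["threshold"] == pytest.approx(0.05)

    def test_constant_column_reported_missing(self):
        df, labels = self._matrix(3)
        df.iloc[:, 2] = 1.0
        res = anova_bonferroni(df, labels)
        assert np.isnan(res["F"].iloc[2])
        assert not res["significant"].iloc[2]


class TestPCA:
    def test_duplicated_column_closed_form(self):
        """Two perfectly correlated columns plus an independent one: the
        correlation matrix has eigenvalues {2, 1, 0}; exactly one exceeds 1."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": y})
        res = pca_kaiser(df)
        lam = np.sort(res.eigenvalues)[::-1]
        # eigenvalues {1 + |r|, 1, 1 - |r|} with r = corr(x, y) ~ 0
        r = abs(np.corrcoef(x, y)[0, 1])
        np.testing.assert_allclose(lam, [2.0, 1.0, 0.0], atol=r + 1e-8)
        assert res.n_retained == 1

    def test_exactly_uncorrelated_columns_retain_nothing(self):
        """With an exactly orthogonal design every eigenvalue is 1, and the
        strict > 1 rule retains none."""
        rng = np.random.default_rng(6)
        m = rng.normal(size=(40, 4))
        q, _ = np.linalg.qr(m - m.mean(axis=0))   # centered, then orthogonal
        df = pd.DataFrame(q, columns=list("abcd"))
        assert np.allclose(np.corrcoef(q, rowvar=False), np.eye(4), atol=1e-10)
        res = pca_kaiser(df)
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=1e-8)
        assert res.n_retained == 0

    def test_varimax_preserves_communalities(self):
        rng = np.random.default_rng(7)
        L = rng.normal(size=(30, 5))
        R = varimax(L)
        np.testing.assert_allclose((R ** 2).sum(axis=1), (L ** 2).sum(axis=1),
                                   atol=1e-8)

    def test_complete_case_dropping_counted(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        df.iloc[0, 0] = np.nan
        res = pca_kaiser(df)
        assert res.n_dropped_rows == 1


class TestSharedVariance:
    def _matrix(self):
        rng = np.random.default_rng(9)
        vals, labels = simulate_strain_values(PAPER_STRAIN_N, 0.5, seed=10)
        df = pd.DataFrame({"p1": vals, "p2": -vals,
                           "p3": rng.normal(size=len(vals))},
                          index=[f"m{i}" for i in range(len(vals))])
        return df, pd.Series(labels, index=df.index)

    def test_self_and_negation_share_everything(self):
        df, labels = self._matrix()
        r2 = shared_genetic_variance(df, labels)
        assert r2.loc["p1", "p1"] == pytest.approx(1.0)
        assert r2.loc["p1", "p2"] == pytest.approx(1.0)

    def test_independent_strain_effects_share_one_over_a_minus_1(self):
        """For independent parameters the null E[r^2] across a=11 strain
        means is 1/(a-1) = 0.1."""
        r2s = []
        for rep in range(300):
            v1, labels = simulate_strain_values(PAPER_STRAIN_N, 0.9, seed=2 * rep)
            v2, _ = simulate_strain_values(PAPER_STRAIN_N, 0.9, seed=2 * rep + 1)
            df = pd.DataFrame({"p1": v1, "p2": v2})
            lab = pd.Series(labels, index=df.index)
            r2s.append(shared_genetic_variance(df, lab).loc["p1", "p2"])
        assert np.mean(r2s) == pytest.approx(0.1, abs=0.02)


class TestCategoryEffectSize:
    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(11)
        names = [f"p{i}" for i in range(115)]
        cats = {n: f"cat{i % 6}" for i, n in enumerate(names)}
        h2 = pd.Series(rng.uniform(0.2, 0.7, 115), index=names)
        res = effectsize_by_category(h2, cats)
        assert res["df"] == (5, 109)

    def test_null_F_near_one(self):
        rng = np.random.default_rng(12)
        names = [f"p{i}" for i in range(600)]
        cats = {n: f"cat{i % 6}" for i, n in enumerate(names)}
        Fs = []
        for rep in range(50):
            h2 = pd.Series(rng.uniform(0, 1, 600), index=names)
            Fs.append(effectsize_by_category(h2, cats)["F"])
        assert np.mean(Fs) == pytest.approx(1.0, abs=0.15)

    def test_degenerate_groups_reported_missing(self):
        names = ["a", "b", "c", "d"]
        cats = {"a": "x", "b": "x", "c": "y", "d": "y"}
        h2 = pd.Series([0.2, 0.2, 0.5, 0.5], index=names)
        res = effectsize_by_category(h2, cats)
        assert np.isnan(res["F"])
        assert res["note"]
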