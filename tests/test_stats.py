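"""Two-sample tests against exhaustive oracles, ICC, VIF, mixed models,
model sets and cross-validation."""
import itertools

import numpy as np
import pandas as pd
import pytest

from sympatry import stats as st
from sympatry.exceptions import InputError, UndefinedResultError


# ---------------------------------------------------------------------------
# independent oracles

def ks_sup_oracle(x, y, alternative="two_sided"):
    """D by direct ECDF evaluation at every pooled point."""
    pts = np.concatenate([x, y])
    fx = np.searchsorted(np.sort(x), pts, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), pts, side="right") / len(y)
    if alternative == "two_sided":
        return np.abs(fx - fy).max()
    if alternative == "greater":   # x stochastically greater: Fx below Fy
        return (fy - fx).max()
    return (fx - fy).max()


def mw_oracle(x, y):
    """U and exact two-sided p by enumerating group assignments and counting
    pairwise wins (ties worth 1/2)."""
    pooled = np.concatenate([x, y])
    n, total = len(x), len(pooled)
    wins = (pooled[:, None] > pooled[None, :]) + \
        0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(wins, 0.0)
    combos = list(itertools.combinations(range(total), n))
    us = np.empty(len(combos))
    for i, c in enumerate(combos):
        sel = np.zeros(total, dtype=bool)
        sel[list(c)] = True
        us[i] = wins[np.ix_(sel, ~sel)].sum()
    obs = wins[np.ix_(np.arange(total) < n, np.arange(total) >= n)].sum()
    lo = (us <= obs + 1e-9).mean()
    hi = (us >= obs - 1e-9).mean()
    return obs, min(1.0, 2.0 * min(lo, hi))


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = st.ks_two_sample(x, x)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_disjoint_supports(self):
        r = st.ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert r.statistic == 1.0

    @pytest.mark.parametrize("alternative",
                             ["two_sided", "greater", "less"])
    def test_statistic_matches_ecdf_oracle(self, alternative):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, m = rng.integers(3, 9, 2)
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, m).astype(float)
            got = st.ks_two_sample(x, y, alternative).statistic
            assert got == pytest.approx(ks_sup_oracle(x, y, alternative),
                                        abs=1e-12)

    def test_too_small_samples_raise(self):
        with pytest.raises(InputError):
            st.ks_two_sample([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_complete_separation_maximises_u(self):
        x = [10.0, 11.0, 12.0, 13.0]
        y = [1.0, 2.0, 3.0]
        r = st.mann_whitney(x, y)
        assert r.statistic == len(x) * len(y)

    def test_identical_samples_give_zero_z(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = st.mann_whitney(x, x)
        assert r.extra["z"] == pytest.approx(0.0)

    def test_all_tied_values(self):
        r = st.mann_whitney([5.0] * 4, [5.0] * 5)
        assert r.extra["z"] == 0.0
        assert r.p_value == 1.0

    def test_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n, m = rng.integers(3, 8, 2)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, m).astype(float)
            u_o, p_o = mw_oracle(x, y)
            r = st.mann_whitney(x, y)
            assert r.statistic == pytest.approx(u_o)
            assert r.p_value == pytest.approx(p_o, abs=0.01)


class TestIcc:
    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 200)
        assert st.icc(v, np.repeat(np.arange(20), 10)) < 0.1

    def test_pure_cluster_structure_gives_one(self):
        rng = np.random.default_rng(1)
        means = rng.normal(0, 1, 20)
        v = np.repeat(means, 10)
        assert st.icc(v, np.repeat(np.arange(20), 10)) == pytest.approx(1.0)

    def test_equal_variance_components_give_half(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(50):
            b = rng.normal(0, 1, 100)
            e = rng.normal(0, 1, (100, 10))
            v = (b[:, None] + e).ravel()
            vals.append(st.icc(v, np.repeat(np.arange(100), 10)))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_monotone_in_between_cluster_variance(self):
        rng = np.random.default_rng(3)
        means = []
        for sb in (0.3, 1.0, 3.0):
            vals = []
            for _ in range(100):
                b = rng.normal(0, sb, 40)
                e = rng.normal(0, 1, (40, 8))
                vals.append(st.icc((b[:, None] + e).ravel(),
                                   np.repeat(np.arange(40), 8)))
            assert all(0.0 <= v <= 1.0 for v in vals)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_single_cluster_raises(self):
        with pytest.raises(UndefinedResultError):
            st.icc([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestDesignHelpers:
    def test_standardize_gives_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(3, 5, 100)})
        out, params = st.standardize(df, ["a"])
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        assert params.iloc[0]["mean"] == pytest.approx(3.0, abs=2.0)

    def test_constant_column_dropped(self):
        df = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        with pytest.warns(UserWarning, match="zero variance"):
            out, _ = st.standardize(df, ["a", "b"])
        assert "a" not in out.columns

    def test_balanced_binary_column_maps_to_unit_values(self):
        df = pd.DataFrame({"a": [0.0, 1.0] * 5})
        out, _ = st.standardize(df, ["a"])
        assert sorted(set(out["a"])) == [pytest.approx(-1.0),
                                         pytest.approx(1.0)]

    def test_vif_orthogonal_predictors_near_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (500, 3)),
                          columns=["a", "b", "c"])
        assert (st.vif(df) < 1.1).all()

    def test_vif_duplicated_column_is_infinite(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        v = st.vif(pd.DataFrame({"a": a, "b": a}))
        assert np.isinf(v).all()

    def test_vif_of_correlated_pair(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 1000)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(0, 1, 1000)
        v = st.vif(pd.DataFrame({"a": a, "b": b}))
        assert v["a"] == pytest.approx(1 / (1 - 0.81), abs=0.6)


class TestMixedModels:
    def test_formula_parsing(self):
        resp, fixed, group = st.parse_formula(
            "depth ~ species + tide + (1|individual)")
        assert resp == "depth"
        assert fixed == ["species", "tide"]
        assert group == "individual"
        assert st.parse_formula("y ~ x")[2] is None

    def test_zero_group_variance_matches_ols(self):
        rng = np.random.default_rng(4)
        n = 600
        x = rng.normal(0, 1, n)
        y = 2.0 + 1.5 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x": x,
                           "g": np.repeat(np.arange(20), 30)})
        lmm = st.fit_mixed("y ~ x + (1|g)", df)
        ols = st.fit_mixed("y ~ x", df)
        assert lmm.re_var < 0.05
        b_lmm = lmm.coef("x")["estimate"]
        b_ols = ols.coef("x")["estimate"]
        assert b_lmm == pytest.approx(b_ols, rel=0.01)

    def test_sqrt_transform_applied(self):
        df = pd.DataFrame({"y": [4.0, 9.0, 16.0, 25.0],
                           "x": [0.0, 1.0, 2.0, 3.0]})
        fit = st.fit_mixed("y ~ x", df, transform="sqrt")
        assert fit.coef("x")["estimate"] == pytest.approx(1.0, abs=1e-8)

    def test_binomial_response_must_be_binary(self):
        df = pd.DataFrame({"y": [0.0, 1.0, 2.0] * 4, "x": range(12)})
        with pytest.raises(InputError):
            st.fit_mixed("y ~ x", df, family="binomial")


class TestModelSet:
    def test_support_boundary_is_strict(self):
        assert st.support_flag([0.0, 1.5, 2.0, 2.5]).tolist() == \
            [True, True, False, False]

    def test_delta_aic_anchored_at_zero_and_flags_consistent(self):
        rng = np.random.default_rng(5)
        n = 400
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        g = np.repeat(np.arange(20), 20)
        y = 1.0 + 2.0 * x1 + rng.normal(0, 1, 20)[g] + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "g": g})
        ms = st.model_set(["y ~ 1 + (1|g)", "y ~ x1 + (1|g)",
                           "y ~ x1 + x2 + (1|g)"], df)
        assert ms.table["delta_aic"].min() == 0.0
        assert (ms.table["supported"] ==
                (ms.table["delta_aic"] < 2.0)).all()
        best = ms.table.loc[ms.table["aic"].idxmin(), "formula"]
        assert "x1" in best


class TestCrossValidation:
    def test_confusion_metrics_hand_oracle(self):
        m = st.confusion_metrics(tp=50, fp=2, fn=50, tn=98)
        assert m["sensitivity"] == pytest.approx(0.50)
        assert m["specificity"] == pytest.approx(0.98)
        assert m["pcc"] == pytest.approx(74.0)
        po, pe = 0.74, (52 * 100 + 148 * 100) / 200 ** 2
        assert m["kappa"] == pytest.approx((po - pe) / (1 - pe))

    def test_separable_data_scores_perfectly(self):
        rng = np.random.default_rng(6)
        n = 200
        y = rng.integers(0, 2, n)
        x = np.where(y == 1, rng.normal(3, 0.3, n), rng.normal(-3, 0.3, n))
        df = pd.DataFrame({"y": y.astype(float), "x": x})
        rep = st.cross_validate("y ~ x", df, folds=5, repeats=2, seed=0)
        s = rep.summary()["mean"]
        assert s["auc"] == pytest.approx(1.0, abs=1e-6)
        assert s["kappa"] == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_labels_score_at_chance(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.normal(0, 1, n)
        y = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        df = pd.DataFrame({"y": y, "x": x})
        rep = st.cross_validate("y ~ x", df, folds=10, repeats=5, seed=1)
        assert rep.summary()["mean"]["auc"] == pytest.approx(0.5, abs=0.07)

    def test_too_few_positives_raise(self):
        df = pd.DataFrame({"y": [1.0] * 3 + [0.0] * 50,
                           "x": np.arange(53.0)})
        with pytest.raises(InputError):
            st.cross_validate("y ~ x", df, folds=10)


class TestProperties:
    from hypothesis import given, settings, strategies as hs

    sample = hs.lists(hs.integers(min_value=0, max_value=9), min_size=3,
                      max_size=8).map(lambda v: np.asarray(v, dtype=float))

    @given(x=sample, y=sample)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mann_whitney_u_statistics_sum_to_nm(self, x, y):
        u_xy = st.mann_whitney(x, y).statistic
        u_yx = st.mann_whitney(y, x).statistic
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    @given(x=sample, y=sample)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ks_one_sided_statistics_bound_the_two_sided(self, x, y):
        d = st.ks_two_sample(x, y).statistic
        dg = st.ks_two_sample(x, y, "greater").statistic
        dl = st.ks_two_sample(x, y, "less").statistic
        assert d == pytest.approx(max(dg, dl))
        assert 0.0 <= d <= 1.0

    @given(vals=hs.lists(hs.floats(-100, 100), min_size=8, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_icc_always_in_unit_interval(self, vals):
        v = np.asarray(vals)
        clusters = np.arange(v.size) % 4
        assert 0.0 <= st.icc(v, clusters) <= 1.0


class TestGate:
    def test_low_icc_routes_to_ks(self):
        rng = np.random.default_rng(8)
        x = rng.normal(30, 5, 100)
        y = rng.normal(35, 5, 100)
        cx = np.repeat(np.arange(5), 20)
        res = st.gated_comparison(x, y, cx, cx)
        assert res["method"] == "ks"
        assert res["icc"] < 0.3

    def test_high_icc_routes_to_lmm(self):
        rng = np.random.default_rng(9)
        bx = rng.normal(0, 10, 5)
        x = 30 + np.repeat(bx, 20) + rng.normal(0, 1, 100)
        y = 35 + np.repeat(rng.normal(0, 10, 5), 20) + rng.normal(0, 1, 100)
        res = st.gated_comparison(x, y, np.repeat(np.arange(5), 20),
                                  np.repeat(np.arange(5, 10), 20))
        assert res["method"] == "lmm"
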