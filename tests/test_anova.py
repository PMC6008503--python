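"""Mixed ANOVA, sphericity correction, simple effects, and FDR."""

import numpy as np
import pytest

from taskcpca.anova import bh_fdr, gg_epsilon, mixed_anova, simple_effects


def brute_force_anova(y, groups):
    """Loop-based cell-means sums-of-squares oracle (balanced designs)."""
    n, T, F = y.shape
    levels = list(dict.fromkeys(groups))
    gi = np.array([levels.index(g) for g in groups])
    ng = {g: int((gi == g).sum()) for g in range(len(levels))}
    grand = y.mean()

    def m_sub(i): return y[i].mean()
    def m_grp(g): return y[gi == g].mean()
    def m_t(t): return y[:, t, :].mean()
    def m_f(f): return y[:, :, f].mean()
    def m_gt(g, t): return y[gi == g, t, :].mean()
    def m_gf(g, f): return y[gi == g, :, f].mean()
    def m_tf(t, f): return y[:, t, f].mean()
    def m_gtf(g, t, f): return y[gi == g, t, f].mean()
    def m_it(i, t): return y[i, t, :].mean()
    def m_if(i, f): return y[i, :, f].mean()

    ss = {}
    ss["group"] = T * F * sum(ng[g] * (m_grp(g) - grand) ** 2 for g in ng)
    ss["sw"] = T * F * sum((m_sub(i) - m_grp(gi[i])) ** 2 for i in range(n))
    ss["time"] = n * F * sum((m_t(t) - grand) ** 2 for t in range(T))
    ss["time:group"] = F * sum(
        ng[g] * (m_gt(g, t) - m_grp(g) - m_t(t) + grand) ** 2
        for g in ng for t in range(T))
    ss["ts"] = F * sum(
        (m_it(i, t) - m_sub(i) - m_gt(gi[i], t) + m_grp(gi[i])) ** 2
        for i in range(n) for t in range(T))
    ss["force"] = n * T * sum((m_f(f) - grand) ** 2 for f in range(F))
    ss["force:group"] = T * sum(
        ng[g] * (m_gf(g, f) - m_grp(g) - m_f(f) + grand) ** 2
        for g in ng for f in range(F))
    ss["fs"] = T * sum(
        (m_if(i, f) - m_sub(i) - m_gf(gi[i], f) + m_grp(gi[i])) ** 2
        for i in range(n) for f in range(F))
    ss["time:force"] = n * sum(
        (m_tf(t, f) - m_t(t) - m_f(f) + grand) ** 2
        for t in range(T) for f in range(F))
    ss["time:force:group"] = sum(
        ng[g] * (m_gtf(g, t, f) - m_gt(g, t) - m_gf(g, f) - m_tf(t, f)
                 + m_grp(g) + m_t(t) + m_f(f) - grand) ** 2
        for g in ng for t in range(T) for f in range(F))
    ss["tfs"] = sum(
        (y[i, t, f] - m_it(i, t) - m_if(i, f) - m_gtf(gi[i], t, f)
         + m_sub(i) + m_gt(gi[i], t) + m_gf(gi[i], f) - m_grp(gi[i])) ** 2
        for i in range(n) for t in range(T) for f in range(F))

    a = len(levels)
    dfe = {"group": n - a, "time": (T - 1) * (n - a),
           "time:group": (T - 1) * (n - a), "force": (F - 1) * (n - a),
           "force:group": (F - 1) * (n - a),
           "time:force": (T - 1) * (F - 1) * (n - a),
           "time:force:group": (T - 1) * (F - 1) * (n - a)}
    dff = {"group": a - 1, "time": T - 1, "time:group": (T - 1) * (a - 1),
           "force": F - 1, "force:group": (F - 1) * (a - 1),
           "time:force": (T - 1) * (F - 1),
           "time:force:group": (T - 1) * (F - 1) * (a - 1)}
    err = {"group": "sw", "time": "ts", "time:group": "ts", "force": "fs",
           "force:group": "fs", "time:force": "tfs",
           "time:force:group": "tfs"}
    return {e: (ss[e] / dff[e]) / (ss[err[e]] / dfe[e]) for e in dff}


class TestMixedAnova:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(4, 2, 2))
        groups = np.array(["a", "a", "b", "b"])
        rep = mixed_anova(y, groups)
        oracle = brute_force_anova(y, groups)
        for effect, Fo in oracle.items():
            assert rep.effect(effect)["F"] == pytest.approx(Fo, abs=1e-10)

    def test_matches_oracle_unbalanced_groups_full_design(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(9, 6, 2))
        groups = np.array(["a"] * 5 + ["b"] * 4)
        rep = mixed_anova(y, groups)
        oracle = brute_force_anova(y, groups)
        for effect, Fo in oracle.items():
            assert rep.effect(effect)["F"] == pytest.approx(Fo, abs=1e-10)

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(8, 3, 2))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        base = mixed_anova(y, groups).table["F"].to_numpy()
        shifted = mixed_anova(y + 7.3, groups).table["F"].to_numpy()
        scaled = mixed_anova(y * 3.1 - 2.0, groups).table["F"].to_numpy()
        assert np.allclose(base, shifted, atol=1e-9)
        assert np.allclose(base, scaled, atol=1e-9)

    def test_partial_eta_squared_in_range(self):
        rng = np.random.default_rng(3)
        rep = mixed_anova(rng.normal(size=(10, 6, 2)),
                          np.array(["a"] * 5 + ["b"] * 5))
        assert ((rep.table["eta_p2"] >= 0) & (rep.table["eta_p2"] <= 1)).all()

    def test_missing_cells_rejected(self):
        y = np.random.default_rng(4).normal(size=(6, 3, 2))
        y[0, 1, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(y, np.array(["a"] * 3 + ["b"] * 3))

    def test_planted_group_effect_detected(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(20, 6, 2))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        y[10:] += 2.0
        rep = mixed_anova(y, groups)
        assert rep.effect("group")["p"] < 1e-4


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        S = 0.4 * np.ones((5, 5)) + 0.6 * np.eye(5)
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_rank_one_gives_lower_bound(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        S = np.outer(v, v)
        assert gg_epsilon(S) == pytest.approx(1.0 / 3.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(6, 6))
        S = A @ A.T
        k = 6
        mean_all = S.mean()
        mean_diag = np.trace(S) / k
        row_means = S.mean(axis=1)
        num = (k * (mean_diag - mean_all)) ** 2
        den = (k - 1) * (np.sum(S ** 2) - 2 * k * np.sum(row_means ** 2)
                         + k ** 2 * mean_all ** 2)
        assert gg_epsilon(S) == pytest.approx(num / den, abs=1e-10)

    def test_non_symmetric_rejected(self):
        S = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError, match="symmetric"):
            gg_epsilon(S)

    def test_bounds_on_random_covariances(self):
        rng = np.random.default_rng(7)
        for k in (3, 6):
            A = rng.normal(size=(k, k + 2))
            eps = gg_epsilon(A @ A.T)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


class TestBhFdr:
    def test_step_up_by_hand(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSimpleEffects:
    def test_planted_force_effect_found_at_exact_bins(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(20, 6, 2))
        y[:, [1, 2], 1] += 1.5  # force effect at bins 2 and 3 only
        tab = simple_effects(y, np.array(["a"] * 10 + ["b"] * 10), "force")
        hits = set(tab.loc[tab["p_fdr"] < 0.05, "bin"])
        assert hits == {2, 3}

    def test_null_data_nothing_significant(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(15, 6, 2))
        tab = simple_effects(y, np.array(["a"] * 8 + ["b"] * 7), "group")
        assert (tab["p_fdr"] > 0.05).all()

    def test_single_bin_adjusted_equals_raw(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(12, 1, 2))
        tab = simple_effects(y, np.array(["a"] * 6 + ["b"] * 6), "force")
        assert tab["p_fdr"].iloc[0] == pytest.approx(tab["p"].iloc[0])

    def test_unknown_contrast_rejected(self):
        y = np.zeros((6, 2, 2))
        with pytest.raises(ValueError, match="contrast"):
            simple_effects(y, np.array(["a"] * 6), "banana")
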