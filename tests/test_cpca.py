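"""Constrained PCA core: oracle equivalence, rotation, predictor weights."""

import numpy as np
import pandas as pd
import pytest

from taskcpca import design, synthetic
from taskcpca.cpca import (
    fit_cpca,
    predictor_weights,
    scree,
    subject_expression_maps,
    varimax_criterion,
    varimax_rotate,
)
from taskcpca.synthetic import CONTROL


def dense_cpca_oracle(Z, G, n_components):
    """Independent route: explicit normal equations + full SVD."""
    C = np.linalg.solve(G.T @ G, G.T @ Z)
    U, D, Vt = np.linalg.svd(G @ C, full_matrices=False)
    return D, Vt[:n_components].T * D[:n_components]


def align_columns(A, B):
    """Match columns of B to A by |correlation| and fix signs."""
    out = np.zeros_like(A)
    used = set()
    for j in range(A.shape[1]):
        cors = [np.abs(A[:, j] @ B[:, k]) if k not in used else -1
                for k in range(B.shape[1])]
        k = int(np.argmax(cors))
        used.add(k)
        s = np.sign(A[:, j] @ B[:, k]) or 1.0
        out[:, j] = s * B[:, k]
    return out


class TestFitOracle:
    def test_matches_dense_oracle_on_random_problems(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n, p, q = 30, 25, 8
            Z = rng.normal(size=(n, p))
            G = rng.normal(size=(n, q))
            m = fit_cpca(Z, G, 4, rotate=False)
            D, L = dense_cpca_oracle(Z, G, 4)
            assert np.allclose(m.singular_values, D[:len(m.singular_values)],
                               atol=1e-8)
            assert np.allclose(m.loadings, align_columns(m.loadings, L),
                               atol=1e-8)

    def test_identity_design_reduces_to_pca(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(12, 10))
        m = fit_cpca(Z, np.eye(12), 3, rotate=False)
        U, D, Vt = np.linalg.svd(Z, full_matrices=False)
        assert np.allclose(m.singular_values, D, atol=1e-10)
        pca_loadings = Vt[:3].T * D[:3]
        assert np.allclose(np.abs(m.loadings), np.abs(pca_loadings), atol=1e-8)

    def test_exact_low_rank_recovered(self):
        rng = np.random.default_rng(2)
        G = rng.normal(size=(40, 6))
        C0 = rng.normal(size=(6, 2)) @ rng.normal(size=(2, 15))  # rank 2
        m = fit_cpca(G @ C0, G, 2, rotate=False)
        assert len(m.singular_values) == 2
        assert m.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        m = fit_cpca(rng.normal(size=(25, 18)), rng.normal(size=(25, 7)), 3)
        assert m.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(m.singular_values) <= 1e-12).all()

    def test_unrotated_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        m = fit_cpca(rng.normal(size=(30, 20)), rng.normal(size=(30, 8)), 4)
        gram = m.unrotated_scores.T @ m.unrotated_scores
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_rotation_preserves_reconstruction(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(30, 20))
        G = rng.normal(size=(30, 8))
        m = fit_cpca(Z, G, 4)
        before = m.unrotated_scores @ m.unrotated_loadings.T
        after = m.scores @ m.loadings.T
        assert np.allclose(before, after, atol=1e-8)

    def test_n_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="rank"):
            fit_cpca(rng.normal(size=(10, 5)), rng.normal(size=(10, 2)), 3)


class TestVarimax:
    def test_two_component_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        # sparse ground truth mixed by a known rotation
        L0 = np.zeros((40, 2))
        L0[:20, 0] = rng.uniform(1, 2, 20)
        L0[20:, 1] = rng.uniform(1, 2, 20)
        theta = 0.4
        Rm = np.array([[np.cos(theta), -np.sin(theta)],
                       [np.sin(theta), np.cos(theta)]])
        L = L0 @ Rm
        best_angle, best_val = 0.0, -np.inf
        for deg in range(180):
            a = np.deg2rad(deg)
            Rg = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            val = varimax_criterion(L @ Rg)
            if val > best_val:
                best_angle, best_val = deg, val
        rotated, R = varimax_rotate(L)
        found = np.rad2deg(np.arctan2(R[1, 0], R[0, 0])) % 90
        assert abs(found - best_angle % 90) <= 1.0

    def test_fixed_point_of_optimal_loadings(self):
        L = np.zeros((30, 3))
        L[:10, 0] = 2.0
        L[10:20, 1] = 1.5
        L[20:, 2] = 1.0
        rotated, R = varimax_rotate(L)
        perm = np.abs(R)
        assert np.allclose(perm[perm > 0.5], 1.0, atol=1e-6)
        assert np.allclose(np.abs(rotated), np.abs(L), atol=1e-6)

    def test_criterion_never_decreases(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            L = rng.normal(size=(25, 4))
            rotated, _ = varimax_rotate(L)
            assert varimax_criterion(rotated) >= varimax_criterion(L) - 1e-12

    def test_rotation_orthogonal_and_ss_preserved(self):
        rng = np.random.default_rng(9)
        L = rng.normal(size=(30, 3))
        rotated, R = varimax_rotate(L)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert np.sum(rotated ** 2) == pytest.approx(np.sum(L ** 2))


class TestPredictorWeights:
    def test_noiseless_weights_recover_planted_curve(self):
        base = synthetic.SimulationConfig(seed=7)
        motor = [t for t in base.network_templates if t.name == "motor"]
        cfg = synthetic.noiseless(
            synthetic.SimulationConfig(seed=7, network_templates=motor))
        sub = synthetic.simulate_subject(cfg, CONTROL, 42)
        Y = sub.bold.reshape(-1, sub.n_scans).T
        dm = design.build_fir_design(sub.events, sub.n_scans, cfg.tr,
                                     cfg.n_bins, list(cfg.force_levels))
        st = design.stack_subjects([(Y, dm)], ["s1"])
        m = fit_cpca(st.Z, st.G, 1, columns=st.columns)
        w = predictor_weights(m, st.G)
        for cond in cfg.force_levels:
            ww = (w[(w.component == 1) & (w.condition == cond)]
                  .sort_values("bin")["weight"].to_numpy())
            r = np.corrcoef(ww, motor[0].hdr[cond])[0, 1]
            assert abs(r) > 0.99

    def test_zero_scores_zero_weights(self):
        rng = np.random.default_rng(10)
        G = rng.normal(size=(20, 4))
        m = fit_cpca(rng.normal(size=(20, 6)), G, 2)
        m.scores = np.zeros_like(m.scores)
        w = predictor_weights(m, G)
        assert np.allclose(w["weight"], 0.0)

    def test_identical_subjects_identical_weights(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(30, 8))
        ev = pd.DataFrame({"onset": [4.0, 20.0, 36.0],
                           "duration": [3.0] * 3,
                           "condition": ["a", "a", "a"]})
        dm = design.build_fir_design(ev, 30, 2.0, 3)
        st = design.stack_subjects([(Y, dm), (Y, dm)], ["s1", "s2"])
        m = fit_cpca(st.Z, st.G, 2, columns=st.columns)
        w = predictor_weights(m, st.G)
        for k in (1, 2):
            w1 = w[(w.subject == "s1") & (w.component == k)]["weight"].to_numpy()
            w2 = w[(w.subject == "s2") & (w.component == k)]["weight"].to_numpy()
            assert np.allclose(w1, w2, atol=1e-8)


class TestScree:
    def test_clear_elbow_after_first_value(self):
        assert scree(np.array([4.0, 1.0, 1.0, 1.0, 1.0])).suggested == 1

    def test_flat_spectrum_falls_back_to_default(self):
        res = scree(np.full(6, 2.0), default=3)
        assert res.suggested == 3 and res.rule == "flat-fallback"

    def test_four_component_spectrum(self):
        # four strong values standing on a slowly decaying floor
        d = np.concatenate([[50, 38, 30, 20], np.linspace(6, 3, 40)])
        assert scree(d).suggested == 4


def test_expression_maps_identical_subjects_match():
    rng = np.random.default_rng(12)
    Y = rng.normal(size=(30, 8))
    ev = pd.DataFrame({"onset": [4.0, 20.0, 36.0], "duration": [3.0] * 3,
                       "condition": ["a"] * 3})
    dm = design.build_fir_design(ev, 30, 2.0, 3)
    st = design.stack_subjects([(Y, dm), (Y, dm)], ["s1", "s2"])
    m = fit_cpca(st.Z, st.G, 2, columns=st.columns)
    expr = subject_expression_maps(m, st)
    assert np.allclose(expr["s1"], expr["s2"], atol=1e-8)
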