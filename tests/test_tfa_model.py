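import numpy as np
import pytest

from tfanet import (
    DraftNetwork,
    ModulationTriplet,
    RegulatoryPair,
    admm_lasso,
    e_step,
    fit,
    generate_tfa_dataset,
    init_model,
    lasso_lambda_max,
    m_step_dense,
    m_step_sparse,
    penalized_objective,
    select_active_triplets,
    standardize_rows,
    update_variances,
)
from tfanet.tfa_model import ZERO_TOL, _restricted_lstsq_rows


def random_draft(L, K, N, rng, density=0.5):
    a = rng.random((N, L)) < density
    b = rng.random((L, K)) < density
    b[np.arange(L), np.arange(L)] = True
    return DraftNetwork([f"TF{i}" for i in range(L)],
                        [f"TF{i}" for i in range(L)] +
                        [f"MOD{i}" for i in range(K - L)],
                        [f"TG{i}" for i in range(N)], a, b)


def random_instance(rng, L=3, N=5, K=4, M=10):
    draft = random_draft(L, K, N, rng)
    A = rng.normal(size=(L, K))  # placeholder; real params drawn below
    Q = rng.normal(size=(K, M))
    E = rng.normal(size=(N, M))
    return draft, Q, E


class TestDraftNetwork:
    def test_from_step_results_supports(self):
        pairs = [RegulatoryPair("TF1", "T1", 0.5, 1e-5),
                 RegulatoryPair("TF2", "T2", 0.4, 1e-5)]
        trips = [ModulationTriplet("M1", "TF1", "T1", 0.1, 0.5, 0.001)]
        d = DraftNetwork.from_step_results(pairs, trips)
        assert d.tfs == ["TF1", "TF2"]
        assert d.regulators == ["TF1", "TF2", "M1"]
        assert d.targets == ["T1", "T2"]
        # self-edges always allowed
        assert d.b_support[0, 0] and d.b_support[1, 1]
        assert d.b_support[0, 2]  # M1 -> TF1
        assert not d.b_support[1, 2]
        assert d.a_support[0, 0] and d.a_support[1, 1]
        assert not d.a_support[0, 1]

    def test_missing_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            DraftNetwork(["TF1"], ["TF1"], ["T1"],
                         np.ones((1, 1), bool), np.zeros((1, 1), bool))

    def test_triplet_for_unknown_tf_rejected(self):
        pairs = [RegulatoryPair("TF1", "T1", 0.5, 1e-5)]
        trips = [ModulationTriplet("M1", "TFX", "T1", 0.1, 0.5, 0.001)]
        with pytest.raises(ValueError, match="TFX"):
            DraftNetwork.from_step_results(pairs, trips)


class TestInitModel:
    def test_single_tf_activity_is_own_mrna(self):
        d = random_draft(1, 1, 2, np.random.default_rng(0), density=1.0)
        Q = np.random.default_rng(1).normal(size=(1, 30))
        E = np.vstack([2 * Q[0], -Q[0]]) + 0.01
        m = init_model(d, Q, E, lam=0.0)
        np.testing.assert_array_equal(m.P, Q[:1])

    def test_deterministic(self, small_truth):
        d = small_truth.draft()
        m1 = init_model(d, small_truth.Q, small_truth.E, 1.0, seed=3)
        m2 = init_model(d, small_truth.Q, small_truth.E, 1.0, seed=3)
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.sigma2_E, m2.sigma2_E)

    def test_misaligned_shapes_rejected(self, small_truth):
        d = small_truth.draft()
        with pytest.raises(ValueError, match="match"):
            init_model(d, small_truth.Q[:2], small_truth.E, 1.0)

    def test_objective_decreases_after_one_iteration(self, small_truth):
        d = small_truth.draft()
        model = fit(d, small_truth.Q, small_truth.E, lam=0.0, max_iter=1)
        assert len(model.objective_trace) == 2
        assert model.objective_trace[1] < model.objective_trace[0]
        assert np.isfinite(model.objective_trace).all()


class TestEStep:
    def _model(self, rng, L=3, N=5, K=4, M=10):
        draft = random_draft(L, K, N, rng, density=1.0)
        Q = rng.normal(size=(K, M))
        E = rng.normal(size=(N, M))
        m = init_model(draft, Q, E, 0.0)
        m.A = rng.normal(size=(N, L))
        m.B = rng.normal(size=(L, K))
        m.sigma2_P = rng.uniform(0.2, 2.0, L)
        m.sigma2_E = rng.uniform(0.2, 2.0, N)
        return m, Q, E

    def test_zero_A_gives_prior_mean(self):
        m, Q, E = self._model(np.random.default_rng(4))
        m.A = np.zeros_like(m.A)
        np.testing.assert_allclose(e_step(m, Q, E), m.B @ Q, atol=1e-10)

    def test_noiseless_consistent_data(self):
        m, Q, _ = self._model(np.random.default_rng(5))
        E = m.A @ (m.B @ Q)
        np.testing.assert_allclose(e_step(m, Q, E), m.B @ Q, atol=1e-8)

    def test_matches_independent_dense_solve(self):
        for s in range(20):
            m, Q, E = self._model(np.random.default_rng(100 + s))
            P = e_step(m, Q, E)
            # independent construction: explicit loops over the normal eqs
            L, N = m.A.shape[1], m.A.shape[0]
            C = np.zeros((L, L))
            for i in range(L):
                for j in range(L):
                    C[i, j] = sum(m.A[n, i] * m.A[n, j] / m.sigma2_E[n]
                                  for n in range(N))
                C[i, i] += 1.0 / m.sigma2_P[i]
            for col in range(Q.shape[1]):
                D = np.array([
                    (m.B @ Q)[i, col] / m.sigma2_P[i]
                    + sum(m.A[n, i] * E[n, col] / m.sigma2_E[n] for n in range(N))
                    for i in range(L)
                ])
                np.testing.assert_allclose(P[:, col], np.linalg.solve(C, D),
                                           atol=1e-10)

    def test_gradient_at_solution_vanishes(self):
        m, Q, E = self._model(np.random.default_rng(6))
        P = e_step(m, Q, E)
        grad = ((P - m.B @ Q) / m.sigma2_P[:, None]
                - m.A.T @ ((E - m.A @ P) / m.sigma2_E[:, None]))
        assert np.max(np.abs(grad)) <= 1e-8


class TestMStepDense:
    def test_exact_recovery_zero_residual(self):
        rng = np.random.default_rng(7)
        d = random_draft(3, 5, 6, rng, density=1.0)
        P = rng.normal(size=(3, 40))
        A_true = rng.normal(size=(6, 3))
        E = A_true @ P
        Q = rng.normal(size=(5, 40))
        A, _ = m_step_dense(P, Q, E, d)
        np.testing.assert_allclose(A, A_true, atol=1e-8)

    def test_orthonormal_rows_pseudoinverse_is_transpose(self):
        rng = np.random.default_rng(8)
        d = random_draft(3, 4, 5, rng, density=1.0)
        P, _ = np.linalg.qr(rng.normal(size=(40, 3)))
        P = P.T  # orthonormal rows
        E = rng.normal(size=(5, 40))
        Q = rng.normal(size=(4, 40))
        A, _ = m_step_dense(P, Q, E, d)
        np.testing.assert_allclose(A, E @ P.T, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        d = random_draft(3, 5, 6, rng, density=0.6)
        P = rng.normal(size=(3, 40))
        Q = rng.normal(size=(5, 40))
        E = rng.normal(size=(6, 40))
        A, B = m_step_dense(P, Q, E, d)
        for n in range(6):
            S = np.flatnonzero(d.a_support[n])
            if S.size == 0:
                continue
            X = P[S].T
            w = np.linalg.solve(X.T @ X, X.T @ E[n])
            np.testing.assert_allclose(A[n, S], w, atol=1e-8)
        assert np.all(A[~d.a_support] == 0)
        assert np.all(B[~d.b_support] == 0)

    def test_rank_deficiency_directs_to_sparse(self):
        rng = np.random.default_rng(10)
        d = random_draft(3, 4, 5, rng, density=1.0)
        P = rng.normal(size=(3, 40))
        P[2] = P[0] + P[1]  # rank 2
        with pytest.raises(np.linalg.LinAlgError, match="sparse"):
            m_step_dense(P, rng.normal(size=(4, 40)), rng.normal(size=(5, 40)), d)


class TestAdmmLasso:
    def test_lambda_zero_is_least_squares(self):
        rng = np.random.default_rng(11)
        Phi = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        w0 = admm_lasso(Phi, y, 0.0)
        np.testing.assert_allclose(w0, np.linalg.lstsq(Phi, y, rcond=None)[0],
                                   atol=1e-10)

    def test_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(12)
        Phi = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        lam_max = lasso_lambda_max(Phi, y)
        assert np.all(admm_lasso(Phi, y, lam_max * 1.0001) == 0)
        # just below the threshold something survives
        assert np.any(admm_lasso(Phi, y, lam_max * 0.95) != 0)

    def test_agrees_with_coordinate_descent_oracle(self):
        from sklearn.linear_model import Lasso

        for s in range(20):
            rng = np.random.default_rng(200 + s)
            Phi = rng.normal(size=(20, 8))
            y = rng.normal(size=20)
            lam = rng.uniform(0.5, 10.0)
            w = admm_lasso(Phi, y, lam)
            # sklearn minimizes (1/2n)||y-Xw||^2 + alpha||w||_1
            oracle = Lasso(alpha=lam / (2 * 20), fit_intercept=False,
                           tol=1e-12, max_iter=100_000).fit(Phi, y).coef_
            np.testing.assert_allclose(w, oracle, atol=1e-4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            admm_lasso(np.ones((5, 1)), np.ones(5), -1.0)


class TestMStepSparse:
    def test_lambda_zero_matches_dense(self):
        rng = np.random.default_rng(13)
        d = random_draft(3, 5, 6, rng, density=0.6)
        P = rng.normal(size=(3, 40))
        Q = rng.normal(size=(5, 40))
        E = rng.normal(size=(6, 40))
        Ad, Bd = m_step_dense(P, Q, E, d)
        As, Bs = m_step_sparse(P, Q, E, d, lam=0.0)
        np.testing.assert_allclose(As, Ad, atol=1e-6)
        np.testing.assert_allclose(Bs, Bd, atol=1e-6)

    def test_support_never_violated(self):
        rng = np.random.default_rng(14)
        d = random_draft(4, 8, 10, rng, density=0.4)
        P = rng.normal(size=(4, 60))
        Q = rng.normal(size=(8, 60))
        E = rng.normal(size=(10, 60))
        for lam in (0.0, 1.0, 50.0):
            A, B = m_step_sparse(P, Q, E, d, lam=lam)
            assert np.all(A[~d.a_support] == 0)
            assert np.all(B[~d.b_support] == 0)

    def test_nonzero_count_monotone_in_lambda(self):
        rng = np.random.default_rng(15)
        d = random_draft(4, 8, 10, rng, density=0.6)
        P = rng.normal(size=(4, 60))
        Q = rng.normal(size=(8, 60))
        E = rng.normal(size=(10, 60))
        counts = []
        for lam in (0.0, 5.0, 20.0, 80.0, 320.0):
            A, B = m_step_sparse(P, Q, E, d, lam=lam)
            counts.append(int((np.abs(A) > ZERO_TOL).sum()
                              + (np.abs(B) > ZERO_TOL).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]


class TestVariancesAndObjective:
    def test_zero_residual_hits_floor(self):
        rng = np.random.default_rng(16)
        B = rng.normal(size=(2, 3))
        Q = rng.normal(size=(3, 20))
        P = B @ Q
        A = rng.normal(size=(4, 2))
        E = A @ P
        s2P, s2E = update_variances(P, Q, E, A, B)
        assert np.all(s2P == 1e-8)
        assert np.all(s2E == 1e-8)

    def test_single_sample_mean(self):
        P = np.array([[2.0]])
        Q = np.array([[1.0]])
        B = np.array([[0.5]])
        A = np.array([[1.0]])
        E = np.array([[5.0]])
        s2P, s2E = update_variances(P, Q, E, A, B)
        assert s2P[0] == pytest.approx((2.0 - 0.5) ** 2)
        assert s2E[0] == pytest.approx((5.0 - 2.0) ** 2)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(17)
        P = rng.normal(size=(3, 15))
        Q = rng.normal(size=(5, 15))
        E = rng.normal(size=(4, 15))
        A = rng.normal(size=(4, 3))
        B = rng.normal(size=(3, 5))
        s2P, s2E = update_variances(P, Q, E, A, B)
        for l in range(3):
            direct = np.mean([(P[l, m] - B[l] @ Q[:, m]) ** 2 for m in range(15)])
            assert s2P[l] == pytest.approx(direct, abs=1e-12)
        for n in range(4):
            direct = np.mean([(E[n, m] - A[n] @ P[:, m]) ** 2 for m in range(15)])
            assert s2E[n] == pytest.approx(direct, abs=1e-12)

    def test_objective_monotone_in_residual_scale(self):
        rng = np.random.default_rng(18)
        Q = rng.normal(size=(4, 30))
        P = rng.normal(size=(2, 30))
        E = rng.normal(size=(5, 30))
        A = np.zeros((5, 2))
        B = np.zeros((2, 4))
        s2P, s2E = np.ones(2), np.ones(5)
        o1 = penalized_objective(A, B, P, Q, E, s2P, s2E, 0.0)
        o2 = penalized_objective(A, B, 2 * P, Q, 2 * E, s2P, s2E, 0.0)
        assert o2 > o1

    def test_closed_form_constant_for_zscored_data(self):
        # A=B=0, sigma^2=1, P and E z-scored: every residual row has
        # mean square 1, so the objective is 0.5*(L+N)*M*(1+log 2pi)
        rng = np.random.default_rng(19)
        L, N, M = 3, 7, 50
        P = standardize_rows(rng.normal(size=(L, M)))
        E = standardize_rows(rng.normal(size=(N, M)))
        Q = rng.normal(size=(4, M))
        obj = penalized_objective(np.zeros((N, L)), np.zeros((L, 4)), P, Q, E,
                                  np.ones(L), np.ones(N), 0.0)
        expected = 0.5 * (L + N) * M * (1 + np.log(2 * np.pi))
        assert obj == pytest.approx(expected, rel=1e-12)


class TestFit:
    def test_noiseless_realizable_model(self):
        t = generate_tfa_dataset(L=3, K=8, N=15, M=150, support_density=0.3,
                                 noise_sd_P=0.0, noise_sd_E=0.0, seed=20)
        model = fit(t.draft(), t.Q, t.E, lam=0.0, max_iter=200,
                    standardize=False)
        assert np.linalg.norm(t.E - model.A @ model.P) < 1e-6
        assert np.linalg.norm(model.P - model.B @ t.Q) < 1e-6

    def test_activity_recovery(self, small_truth):
        model = fit(small_truth.draft(), small_truth.Q, small_truth.E,
                    lam=0.0, max_iter=100)
        cors = [abs(np.corrcoef(model.P[l], small_truth.P_true[l])[0, 1])
                for l in range(3)]
        assert np.median(cors) >= 0.8

    def test_objective_trace_non_increasing(self, small_truth):
        model = fit(small_truth.draft(), small_truth.Q, small_truth.E,
                    lam=50.0, max_iter=40)
        diffs = np.diff(model.objective_trace)
        assert np.all(diffs <= 1e-9)

    def test_support_preserved_through_fit(self, small_truth):
        d = small_truth.draft()
        model = fit(d, small_truth.Q, small_truth.E, lam=20.0, max_iter=20)
        assert np.all(model.A[~d.a_support] == 0)
        assert np.all(model.B[~d.b_support] == 0)


class TestSelectActiveTriplets:
    def _fitted(self, lam):
        t = generate_tfa_dataset(L=3, K=10, N=12, M=150, support_density=0.4,
                                 noise_sd_P=0.2, noise_sd_E=0.2, seed=21)
        trips = [ModulationTriplet(m, tf, tg, 0.1, 0.3, 0.001)
                 for (m, tf, tg) in t.gated_triplets]
        model = fit(t.draft(), t.Q, t.E, lam=lam, max_iter=30)
        return model, trips

    def test_selection_matches_brute_force_scan(self):
        model, trips = self._fitted(lam=400.0)
        selected = select_active_triplets(model, trips)
        d = model.draft
        tf_i = {x: i for i, x in enumerate(d.tfs)}
        reg_i = {x: i for i, x in enumerate(d.regulators)}
        tg_i = {x: i for i, x in enumerate(d.targets)}
        expected = [t for t in trips
                    if abs(model.B[tf_i[t.tf], reg_i[t.modulator]]) > ZERO_TOL
                    and abs(model.A[tg_i[t.target], tf_i[t.tf]]) > ZERO_TOL]
        assert selected == expected

    def test_strong_penalty_prunes_some_triplets(self):
        model, trips = self._fitted(lam=400.0)
        selected = select_active_triplets(model, trips)
        assert len(selected) < len(trips)

    def test_zero_beta_excludes_triplet(self):
        model, trips = self._fitted(lam=0.0)
        model.B[:] = 0.0
        assert select_active_triplets(model, trips) == []


def test_restricted_lstsq_rows_empty_support():
    Y = np.ones((2, 5))
    X = np.ones((3, 5))
    support = np.zeros((2, 3), bool)
    W = _restricted_lstsq_rows(Y, X, support)
    assert np.all(W == 0)
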