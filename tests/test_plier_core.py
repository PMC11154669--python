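"""Factorization core: objective, block updates, initialization, fit properties."""

import numpy as np
import pytest
from scipy import optimize

from plierlite import (
    PlierConfig,
    fit,
    init_factors,
    lv_gene_sparsity,
    lv_pathway_counts,
    objective,
    select_num_lvs,
    update_B,
    update_U,
    update_Z,
)
from plierlite import generate_compendium, generate_prior
from plierlite.plier import top_set_per_lv


def brute_force_objective(Y, C, Z, B, U, l1, l2, l3):
    """Independent elementwise summation of the four objective terms."""
    total = 0.0
    R = Y - Z @ B
    for i in range(R.shape[0]):
        for j in range(R.shape[1]):
            total += R[i, j] ** 2
    A = Z - C @ U
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            total += l1 * A[i, j] ** 2
    for i in range(B.shape[0]):
        for j in range(B.shape[1]):
            total += l2 * B[i, j] ** 2
    for i in range(U.shape[0]):
        for j in range(U.shape[1]):
            total += l3 * abs(U[i, j])
    return total


class TestObjective:
    def test_all_zero_matrices_give_zero(self):
        z = np.zeros((3, 2))
        assert objective(np.zeros((3, 4)), np.zeros((3, 5)), z,
                         np.zeros((2, 4)), np.zeros((5, 2)), 1, 1, 1) == 0.0

    def test_hand_evaluated_one_by_one_case(self):
        one = np.ones((1, 1))
        # Y=ZB so term1=0; Z=CU so term2=0; ||B||^2=1; ||U||_1=1
        assert objective(one, one, one, one, one, 1, 1, 1) == pytest.approx(2.0)

    def test_matches_elementwise_brute_force(self, rng):
        Y = rng.normal(size=(5, 4))
        C = rng.integers(0, 2, size=(5, 3)).astype(float)
        Z = rng.normal(size=(5, 2))
        B = rng.normal(size=(2, 4))
        U = rng.normal(size=(3, 2))
        got = objective(Y, C, Z, B, U, 0.7, 1.3, 0.2)
        want = brute_force_objective(Y, C, Z, B, U, 0.7, 1.3, 0.2)
        assert got == pytest.approx(want, abs=1e-10)

    def test_shape_mismatch_names_the_pair(self, rng):
        Y = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="Z .* B"):
            objective(Y, np.zeros((5, 3)), np.zeros((5, 2)), np.zeros((3, 4)),
                      np.zeros((3, 3)), 1, 1, 1)


class TestInitFactors:
    def test_exact_rank_data_reconstructed(self, rng):
        Y = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 15))
        Z0, B0 = init_factors(Y, 3)
        assert np.linalg.norm(Y - Z0 @ B0) < 1e-8 * np.linalg.norm(Y)

    def test_reconstruction_error_equals_discarded_singular_mass(self, rng):
        Y = rng.normal(size=(12, 9))
        s = np.linalg.svd(Y, compute_uv=False)
        for k in (1, 3, 5):
            Z0, B0 = init_factors(Y, k)
            err = np.linalg.norm(Y - Z0 @ B0)
            assert err == pytest.approx(np.sqrt(np.sum(s[k:] ** 2)), rel=1e-10)

    def test_rank_one_outer_product_recovered(self, rng):
        u, v = rng.normal(size=8), rng.normal(size=5)
        Y = np.outer(u, v)
        Z0, B0 = init_factors(Y, 1)
        assert np.linalg.norm(Y - Z0 @ B0) < 1e-8

    def test_too_many_lvs_rejected(self, rng):
        with pytest.raises(ValueError, match="n_lvs"):
            init_factors(rng.normal(size=(4, 6)), 5)


class TestSelectNumLvs:
    def test_recovers_planted_rank_noiseless(self, small_prior):
        prior, _ = small_prior
        expr, _, _ = generate_compendium(prior, 6, 4, 4, 20, noise_sd=0.0, seed=13)
        assert select_num_lvs(expr.values) == 6

    def test_pure_noise_yields_at_most_three(self):
        results = []
        for seed in range(20):
            Y = np.random.default_rng(seed).normal(size=(200, 80))
            results.append(select_num_lvs(Y))
        assert max(results) <= 3

    def test_noise_rarely_inflates_planted_rank(self, small_prior):
        prior, _ = small_prior
        exceed = 0
        for seed in range(20):
            expr, _, _ = generate_compendium(prior, 6, 4, 4, 20, noise_sd=0.5, seed=seed)
            exceed += select_num_lvs(expr.values) > 6
        assert exceed <= 1

    def test_deterministic_for_fixed_input(self, rng):
        Y = rng.normal(size=(50, 30))
        assert select_num_lvs(Y) == select_num_lvs(Y)


def ridge_rows_oracle(Y, Z, lam):
    """Per-sample ridge via an augmented least-squares system (lstsq)."""
    L = Z.shape[1]
    A = np.vstack([Z, np.sqrt(lam) * np.eye(L)])
    B = np.empty((L, Y.shape[1]))
    for j in range(Y.shape[1]):
        b = np.concatenate([Y[:, j], np.zeros(L)])
        B[:, j] = np.linalg.lstsq(A, b, rcond=None)[0]
    return B


class TestUpdateB:
    def test_identity_loadings_no_ridge_returns_Y(self, rng):
        Y = rng.normal(size=(3, 5))
        np.testing.assert_allclose(update_B(Y, np.eye(3), 0.0), Y)

    def test_hand_solved_identity_with_ridge(self):
        Y = np.array([[2.0], [2.0]])
        np.testing.assert_allclose(update_B(Y, np.eye(2), 1.0), [[1.0], [1.0]])

    def test_matches_augmented_lstsq_oracle(self, rng):
        Y = rng.normal(size=(25, 12))
        Z = rng.normal(size=(25, 6))
        for lam in (0.1, 1.0, 10.0):
            np.testing.assert_allclose(update_B(Y, Z, lam),
                                       ridge_rows_oracle(Y, Z, lam), atol=1e-8)

    def test_is_local_minimum_of_penalized_objective(self, rng):
        Y = rng.normal(size=(10, 6))
        Z = rng.normal(size=(10, 4))
        lam = 0.7
        B = update_B(Y, Z, lam)
        base = np.sum((Y - Z @ B) ** 2) + lam * np.sum(B**2)
        for _ in range(100):
            P = B + rng.normal(scale=1e-3, size=B.shape)
            assert np.sum((Y - Z @ P) ** 2) + lam * np.sum(P**2) >= base - 1e-12

    def test_singular_system_without_ridge_advises_positive_lambda2(self, rng):
        Z = np.zeros((4, 2))
        with pytest.raises(np.linalg.LinAlgError, match="positive lambda2"):
            update_B(rng.normal(size=(4, 3)), Z, 0.0)


class TestUpdateZ:
    def test_limit_of_vanishing_prior_weight_is_projection_onto_Y(self, rng):
        Y = rng.normal(size=(6, 6))
        B = np.eye(6)
        C = np.zeros((6, 2))
        U = np.zeros((2, 6))
        Z = update_Z(Y, B, C, U, 1e-12)
        np.testing.assert_allclose(Z, Y, atol=1e-9)

    def test_prior_only_solution_is_CU(self, rng):
        C = rng.integers(0, 2, size=(8, 3)).astype(float)
        U = np.abs(rng.normal(size=(3, 4)))
        Z = update_Z(np.zeros((8, 5)), np.zeros((4, 5)), C, U, 2.0)
        np.testing.assert_allclose(Z, C @ U, atol=1e-12)

    def test_matches_row_wise_augmented_lstsq_oracle(self, rng):
        Y = rng.normal(size=(15, 10))
        B = rng.normal(size=(4, 10))
        C = rng.integers(0, 2, size=(15, 3)).astype(float)
        U = np.abs(rng.normal(size=(3, 4)))
        lam1 = 1.7
        Z = update_Z(Y, B, C, U, lam1)
        target = C @ U
        A = np.vstack([B.T, np.sqrt(lam1) * np.eye(4)])
        for g in range(15):
            b = np.concatenate([Y[g], np.sqrt(lam1) * target[g]])
            z_g = np.linalg.lstsq(A, b, rcond=None)[0]
            np.testing.assert_allclose(Z[g], z_g, atol=1e-8)

    def test_clipping_removes_negative_entries(self, rng):
        Y = rng.normal(size=(10, 8))
        B = rng.normal(size=(3, 8))
        C = np.zeros((10, 2))
        U = np.zeros((2, 3))
        Z = update_Z(Y, B, C, U, 0.5, clip_negative=True)
        assert (Z >= 0).all()


def nnlasso_oracle(z, C, lam1, lam3):
    """Brute-force constrained optimizer for one U column (L-BFGS-B)."""
    k = C.shape[1]

    def f(u):
        r = z - C @ u
        return lam1 * np.dot(r, r) + lam3 * np.sum(u)

    def grad(u):
        return -2 * lam1 * C.T @ (z - C @ u) + lam3

    best = None
    for start in (np.zeros(k), np.full(k, 0.5), np.abs(np.linalg.lstsq(C, z, rcond=None)[0])):
        res = optimize.minimize(f, start, jac=grad, method="L-BFGS-B",
                                bounds=[(0, None)] * k,
                                options={"ftol": 1e-14, "gtol": 1e-12})
        if best is None or res.fun < best:
            best = res.fun
    return best


class TestUpdateU:
    def test_large_lambda3_fully_shrinks(self, rng):
        Z = rng.normal(size=(10, 3))
        C = rng.integers(0, 2, size=(10, 4)).astype(float)
        lam1 = 1.0
        lam3 = 2 * lam1 * np.abs(C.T @ Z).max() + 1e-9
        U = update_U(Z, C, lam1, lam3)
        assert np.abs(U).max() == 0.0

    def test_orthogonal_design_no_l1_gives_clipped_least_squares(self, rng):
        # disjoint sets -> orthogonal columns of C
        C = np.zeros((12, 3))
        C[0:4, 0] = C[4:8, 1] = C[8:12, 2] = 1.0
        Z = rng.normal(size=(12, 2))
        U = update_U(Z, C, 1.0, 0.0, enforce_nonneg=True)
        expected = np.maximum(0.0, np.linalg.lstsq(C, Z, rcond=None)[0])
        np.testing.assert_allclose(U, expected, atol=1e-8)

    def test_objective_matches_brute_force_oracle(self, rng):
        lam1, lam3 = 1.3, 0.8
        for _ in range(5):
            C = rng.integers(0, 2, size=(20, 4)).astype(float)
            C[:, C.sum(axis=0) == 0] = 1.0
            z = rng.normal(size=20)
            U = update_U(z[:, None], C, lam1, lam3)
            r = z - C @ U[:, 0]
            got = lam1 * np.dot(r, r) + lam3 * np.sum(U)
            want = nnlasso_oracle(z, C, lam1, lam3)
            assert got <= want + 1e-6

    def test_zero_gene_set_column_forces_zero_row(self, rng):
        C = np.zeros((10, 2))
        C[:5, 0] = 1.0
        Z = rng.normal(size=(10, 3))
        with pytest.warns(UserWarning, match="all-zero"):
            U = update_U(Z, C, 1.0, 0.1)
        assert (U[1] == 0).all()


class TestFit:
    def test_zero_iterations_returns_initialization(self, small_compendium, small_prior):
        expr, _, _ = small_compendium
        prior, _ = small_prior
        model = fit(expr, prior, PlierConfig(n_lvs=6, max_iterations=0, lambda3=1.0))
        assert len(model.objective_trace) == 1
        assert np.abs(model.U).max() == 0.0
        # (Z, B) is the rank-6 truncated SVD
        s = np.linalg.svd(expr.values, compute_uv=False)
        err = np.linalg.norm(expr.values - model.Z @ model.B)
        assert err == pytest.approx(np.sqrt(np.sum(s[6:] ** 2)), rel=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_trace_never_increases(self, seed):
        prior, _ = generate_prior(120, 6, 12, seed=seed)
        expr, _, _ = generate_compendium(prior, 8, 4, 3, 15, noise_sd=0.4, seed=seed + 30)
        model = fit(expr, prior, PlierConfig(n_lvs=8, max_iterations=60))
        trace = np.array(model.objective_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_nonneg_U_enforced(self, small_compendium, small_prior):
        expr, _, _ = small_compendium
        prior, _ = small_prior
        model = fit(expr, prior, PlierConfig(n_lvs=6, max_iterations=40))
        assert model.U.min() >= 0.0

    def test_non_finite_input_rejected(self, small_prior):
        prior, _ = small_prior
        Y = np.full((100, 12), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            fit(Y, prior.membership, PlierConfig(n_lvs=2))

    def test_misaligned_gene_rows_rejected(self, small_compendium, small_prior):
        expr, _, _ = small_compendium
        prior, _ = small_prior
        shuffled = prior.subset_genes(list(reversed(prior.gene_ids)))
        with pytest.raises(ValueError, match="aligned"):
            fit(expr, shuffled)

    def test_scale_consistency(self, small_compendium, small_prior):
        """Scaling Y by alpha (with lambda2 -> alpha^2 lambda2, lambda3 ->
        alpha lambda3) scales Z and U by alpha, leaves B identical, and
        preserves the U support."""
        expr, _, _ = small_compendium
        prior, _ = small_prior
        alpha = 3.0
        base = PlierConfig(n_lvs=6, lambda1=2.0, lambda2=1.5, lambda3=4.0,
                           max_iterations=25)
        scaled = PlierConfig(n_lvs=6, lambda1=2.0, lambda2=alpha**2 * 1.5,
                             lambda3=alpha * 4.0, max_iterations=25)
        m1 = fit(expr, prior, base)
        m2 = fit(alpha * expr.values, prior.membership, scaled)
        np.testing.assert_allclose(m2.B, m1.B, atol=1e-6)
        np.testing.assert_allclose(m2.Z, alpha * m1.Z, atol=1e-6)
        assert ((m2.U > 1e-8) == (m1.U > 1e-8)).all()


class TestSparsityAndPathwayCounts:
    def _model(self, Z, U=None, set_ids=None):
        from plierlite import PlierModel

        L = Z.shape[1]
        U = U if U is not None else np.zeros((2, L))
        return PlierModel(
            Z=Z, B=np.zeros((L, 3)), U=U, config=PlierConfig(n_lvs=L, lambda3=1.0),
            objective_trace=[0.0], gene_ids=[f"g{i}" for i in range(Z.shape[0])],
            sample_ids=["s0", "s1", "s2"],
            set_ids=set_ids or [f"set{i}" for i in range(U.shape[0])],
        )

    def test_single_nonzero_per_column(self):
        Z = np.zeros((10, 3))
        Z[0, 0] = Z[4, 1] = Z[9, 2] = 2.0
        fractions, mean = lv_gene_sparsity(self._model(Z), tolerance=0.01)
        np.testing.assert_allclose(fractions, 0.9)
        assert mean == pytest.approx(0.9)

    def test_dense_loadings_have_zero_sparsity(self, rng):
        Z = rng.uniform(1.0, 1.5, size=(10, 3))
        fractions, _ = lv_gene_sparsity(self._model(Z), tolerance=0.01)
        np.testing.assert_allclose(fractions, 0.0)

    def test_pathway_counts_trivial_cases(self):
        Z = np.ones((4, 3))
        counts = lv_pathway_counts(self._model(Z, U=np.zeros((2, 3))))
        assert counts.tolist() == [0, 0, 0]
        U = np.zeros((2, 3))
        U[0, 0] = U[1, 1] = U[0, 2] = 0.5
        counts = lv_pathway_counts(self._model(Z, U=U))
        assert counts.tolist() == [1, 1, 1]

    def test_top_set_tie_breaks_to_lowest_index(self):
        Z = np.ones((4, 1))
        U = np.array([[0.5], [0.5]])
        model = self._model(Z, U=U, set_ids=["a", "b"])
        assert top_set_per_lv(model) == ["a"]

    def test_u_support_shrinks_as_lambda3_grows(self, small_compendium, small_prior):
        expr, _, _ = small_compendium
        prior, _ = small_prior
        sL = np.linalg.svd(expr.values, compute_uv=False)[5]
        counts = []
        for lam3 in sL / 2 * np.array([0.5, 2.0, 8.0, 32.0, 128.0]):
            m = fit(expr, prior, PlierConfig(n_lvs=6, lambda3=float(lam3),
                                             max_iterations=30))
            counts.append(int((m.U > 1e-8).sum()))
        assert counts == sorted(counts, reverse=True)
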