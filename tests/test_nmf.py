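import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import mmtraj as mt
from mmtraj.nmf import NMFError, objective


def random_binary(rng, shape, p=0.3):
    A = (rng.random(shape) < p).astype(float)
    # keep at least one entry so the factorisation is non-degenerate
    if A.sum() == 0:
        A[0, 0] = 1.0
    return sp.csr_matrix(A)


def test_objective_matches_dense_computation():
    # the sparse trace-form objective vs the literal dense residual norm
    rng = np.random.default_rng(0)
    A = random_binary(rng, (15, 8))
    W = rng.random((15, 3))
    H = rng.random((3, 8))
    dense = np.linalg.norm(A.toarray() - W @ H) ** 2
    assert objective(A, W, H) == pytest.approx(dense, rel=1e-10)


def test_update_step_monotone_and_nonnegative():
    rng = np.random.default_rng(1)
    A = random_binary(rng, (20, 10))
    W = rng.random((20, 3)) + 0.1
    H = rng.random((3, 10)) + 0.1
    prev = objective(A, W, H)
    for _ in range(200):
        W, H = mt.update_step(W, H, A)
        cur = objective(A, W, H)
        assert cur <= prev + 1e-10 * max(prev, 1.0)
        assert (W >= 0).all() and (H >= 0).all()
        prev = cur


def test_tracked_loss_equals_recomputed_objective():
    rng = np.random.default_rng(2)
    A = random_binary(rng, (30, 12))
    fit = mt.factorize(A, 3, n_restarts=2, max_iter=50, seed=9)
    assert fit.loss == pytest.approx(objective(A, fit.W, fit.H), rel=1e-8)


def test_exact_rank_one_recovery():
    A = sp.csr_matrix(np.outer([1.0, 2.0, 3.0], [4.0, 0.0, 5.0]))
    fit = mt.factorize(A, 1, n_restarts=3, max_iter=500, tol=1e-12, seed=0)
    rel = np.sqrt(fit.loss) / sp.linalg.norm(A)
    assert rel < 1e-3


def test_identity_recovered_at_full_rank():
    A = sp.csr_matrix(np.eye(2))
    fit = mt.factorize(A, 2, n_restarts=10, max_iter=2000, tol=1e-14, seed=1)
    assert np.sqrt(fit.loss) < 1e-2
    # W H is a scaled permutation of the identity
    np.testing.assert_allclose(fit.W @ fit.H, np.eye(2), atol=0.05)


def test_factorize_is_deterministic(planted_matrix):
    a = mt.factorize(planted_matrix, 3, n_restarts=2, max_iter=30, seed=4)
    b = mt.factorize(planted_matrix, 3, n_restarts=2, max_iter=30, seed=4)
    np.testing.assert_array_equal(a.W, b.W)
    np.testing.assert_array_equal(a.H, b.H)
    assert a.loss == b.loss and a.restart_id == b.restart_id


def test_degenerate_inputs_rejected():
    rng = np.random.default_rng(3)
    A = random_binary(rng, (5, 4))
    with pytest.raises(NMFError):
        mt.factorize(A, 5)  # k > min(u, v)
    with pytest.raises(NMFError):
        mt.factorize(sp.csr_matrix((5, 4)), 2)  # all-zero matrix


def test_fit_metrics_hand_values():
    A = sp.csr_matrix(np.ones((2, 2)))
    W = np.full((2, 1), 1.0)
    H = np.full((1, 2), 0.5)
    m = mt.fit_metrics(A, W, H)
    assert m["mse"] == pytest.approx(0.25)  # (1 - 0.5)^2 per cell
    # per cell: 1*ln(1/0.5) - 1 + 0.5
    assert m["kl_divergence"] == pytest.approx(4 * (np.log(2.0) - 0.5))


def test_perfect_reconstruction_metrics_are_zero():
    W = np.array([[1.0], [2.0]])
    H = np.array([[3.0, 1.0]])
    A = sp.csr_matrix(W @ H)
    m = mt.fit_metrics(A, W, H)
    assert m["mse"] == pytest.approx(0.0, abs=1e-12)
    assert m["kl_divergence"] == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_kl_divergence_nonnegative(seed):
    rng = np.random.default_rng(seed)
    A = random_binary(rng, (10, 6))
    W = rng.random((10, 2)) + 0.01
    H = rng.random((2, 6)) + 0.01
    assert mt.fit_metrics(A, W, H)["kl_divergence"] >= 0.0


def test_cophenetic_identical_runs_is_one():
    rng = np.random.default_rng(5)
    H = rng.random((3, 20))
    runs = [mt.FactorizationResult(W=None, H=H, k=3, loss=0, n_iter=0,
                                   restart_id=i, seed=0) for i in range(5)]
    assert mt.cophenetic_coefficient(runs) == 1.0


def test_cophenetic_random_assignments_below_one():
    rng = np.random.default_rng(6)
    runs = []
    for i in range(10):
        H = np.zeros((4, 50))
        H[rng.integers(0, 4, 50), np.arange(50)] = 1.0
        runs.append(mt.FactorizationResult(W=None, H=H, k=4, loss=0,
                                           n_iter=0, restart_id=i, seed=0))
    assert mt.cophenetic_coefficient(runs) < 0.9


def test_cophenetic_three_leaf_hand_case():
    # two runs, three conditions; consensus pairs (1,2)=1, (1,3)=(2,3)=0.5.
    # Average linkage reproduces those distances exactly, so the cophenetic
    # correlation is 1 (computed by hand on the 3-leaf dendrogram).
    def h_for(assign):
        H = np.zeros((2, 3))
        H[assign, np.arange(3)] = 1.0
        return H

    runs = [
        mt.FactorizationResult(W=None, H=h_for([0, 0, 0]), k=2, loss=0,
                               n_iter=0, restart_id=0, seed=0),
        mt.FactorizationResult(W=None, H=h_for([0, 0, 1]), k=2, loss=0,
                               n_iter=0, restart_id=1, seed=0),
    ]
    assert mt.cophenetic_coefficient(runs) == pytest.approx(1.0)


def test_rank_scan_single_k_and_determinism(planted_matrix):
    a = mt.rank_scan(planted_matrix, (3, 3), runs_per_k=2, max_iter=30, seed=8)
    assert len(a.records) == 1 and a.records[0]["k"] == 3
    b = mt.rank_scan(planted_matrix, (3, 3), runs_per_k=2, max_iter=30, seed=8)
    assert a.records == b.records


def test_best_loss_not_worse_than_sklearn_mu():
    # independent implementation cross-check: scikit-learn's multiplicative
    # -update NMF on the same matrix should reach a similar Frobenius loss
    sklearn = pytest.importorskip("sklearn.decomposition")
    rng = np.random.default_rng(11)
    A = random_binary(rng, (60, 25), p=0.25)
    ours = mt.factorize(A, 4, n_restarts=10, max_iter=400, tol=1e-7, seed=0)
    model = sklearn.NMF(
        n_components=4, solver="mu", beta_loss="frobenius", init="random",
        max_iter=400, tol=1e-7, random_state=0,
    )
    W = model.fit_transform(A.toarray())
    theirs = np.linalg.norm(A.toarray() - W @ model.components_) ** 2
    assert ours.loss <= theirs * 1.05
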