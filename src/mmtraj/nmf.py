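"""Non-negative matrix factorisation with multiplicative updates.

Factorises the sparse binary person-time matrix A (u x v) into W (u x k)
and H (k x v), both non-negative: the rows of H are *disease clusters*
(weighted groups of co-occurring conditions) and the rows of W give each
person-year's expression of every cluster.

The Frobenius objective ||A - WH||_F^2 is minimised with the classical
multiplicative update rules

    H <- H * (W'A) / (W'W H),      W <- W * (A H') / (W H H'),

which keep both factors non-negative and never increase the objective.
Because A is sparse and binary, both the updates and the objective are
evaluated without ever forming the dense u x v product WH:

    ||A - WH||^2 = nnz(A) - 2 <W'A, H> + <W'W, HH'>,

so each iteration costs O(nnz(A) k + (u + v) k^2).  The generalised
Kullback-Leibler divergence D(A || WH) is reported alongside as a second
fit diagnostic.

NMF is non-convex: every factorisation is restarted from multiple random
initialisations (seeded deterministically per restart) and the lowest-loss
restart is kept.  Rank selection is supported by a scan that records
fit (MSE, KL) and stability (cophenetic correlation of the condition
co-assignment consensus) for each candidate k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from .matrix import PersonTimeMatrix

EPS_FLOOR = 1e-12  # elementwise floor on W, H: avoids division by zero
_DIV_EPS = 1e-12


class NMFError(RuntimeError):
    pass


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    k: int
    loss: float  # final ||A - WH||_F^2
    n_iter: int
    restart_id: int
    seed: int
    loss_history: np.ndarray = field(repr=False, default=None)


@dataclass
class RankScanReport:
    records: "list[dict]"
    k_range: tuple[int, int]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def suggest_elbow(self, metric: str = "mse") -> int:
        """k with the maximal second difference of the fit curve.

        Advisory only: the final rank is a user decision that weighs fit,
        complexity, stability and interpretability.
        """
        ks = [r["k"] for r in self.records]
        ys = np.array([r[metric] for r in self.records], dtype=float)
        if len(ks) < 3:
            return ks[int(np.argmin(ys))]
        second = ys[:-2] - 2 * ys[1:-1] + ys[2:]
        return ks[int(np.argmax(second)) + 1]


def _sq_frobenius(A: sp.csr_matrix, W: np.ndarray, H: np.ndarray, nnz_sq: float) -> float:
    """||A - WH||_F^2 without forming WH (A sparse)."""
    AtW = A.T @ W  # v x k
    cross = float(np.sum(AtW * H.T))
    gram = float(np.sum((W.T @ W) * (H @ H.T)))
    return max(nnz_sq - 2.0 * cross + gram, 0.0)


def objective(A: sp.csr_matrix, W: np.ndarray, H: np.ndarray) -> float:
    """Squared Frobenius reconstruction error ||A - WH||_F^2."""
    A = sp.csr_matrix(A)
    return _sq_frobenius(A, W, H, float((A.data**2).sum()))


def update_step(
    W: np.ndarray, H: np.ndarray, A: sp.csr_matrix
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update of H then W for the Frobenius objective."""
    A = sp.csr_matrix(A)
    WtA = (A.T @ W).T  # k x v
    H = H * (WtA / ((W.T @ W) @ H + _DIV_EPS))
    np.maximum(H, EPS_FLOOR, out=H)
    AHt = A @ H.T  # u x k
    W = W * (AHt / (W @ (H @ H.T) + _DIV_EPS))
    np.maximum(W, EPS_FLOOR, out=W)
    if not (np.isfinite(W).all() and np.isfinite(H).all()):
        raise NMFError("non-finite value appeared during a multiplicative update")
    return W, H


def _as_sparse(A) -> sp.csr_matrix:
    if isinstance(A, PersonTimeMatrix):
        A = A.A
    A = sp.csr_matrix(A, dtype=np.float64)
    if (A.data < 0).any():
        raise NMFError("A must be non-negative")
    return A


def factorize(
    A,
    k: int,
    n_restarts: int = 100,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
) -> FactorizationResult:
    """Best-of-``n_restarts`` multiplicative-update NMF at rank ``k``.

    Each restart initialises W and H with uniform random values (restart r
    uses seed ``seed + r``, so reruns are bit-identical) and iterates until
    the relative loss change drops below ``tol`` or ``max_iter`` is reached.
    The restart with the lowest final loss wins; ties go to the lowest
    restart id.
    """
    A = _as_sparse(A)
    u, v = A.shape
    if not 1 <= k <= min(u, v):
        raise NMFError(f"rank k={k} outside [1, min(u, v)={min(u, v)}]")
    if A.nnz == 0:
        raise NMFError("A is all-zero: factorisation is degenerate")

    nnz_sq = float((A.data**2).sum())
    mean_a = A.data.sum() / (u * v)
    scale = np.sqrt(mean_a / k)

    best: FactorizationResult | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        W = np.maximum(scale * rng.random((u, k)), EPS_FLOOR)
        H = np.maximum(scale * rng.random((k, v)), EPS_FLOOR)
        loss = _sq_frobenius(A, W, H, nnz_sq)
        history = [loss]
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            W, H = update_step(W, H, A)
            new_loss = _sq_frobenius(A, W, H, nnz_sq)
            history.append(new_loss)
            if abs(loss - new_loss) <= tol * max(loss, _DIV_EPS):
                loss = new_loss
                break
            loss = new_loss
        if best is None or loss < best.loss:
            best = FactorizationResult(
                W=W,
                H=H,
                k=k,
                loss=loss,
                n_iter=n_iter,
                restart_id=r,
                seed=seed,
                loss_history=np.asarray(history),
            )
    return best


def fit_metrics(A, W: np.ndarray, H: np.ndarray) -> dict[str, float]:
    """Fit diagnostics: mean squared error and generalised KL divergence.

    mse averages (A - WH)^2 over all u*v cells.  The KL divergence is
    D(A || WH) = sum a*ln(a/b) - a + b with the 0*ln(0) = 0 convention.
    """
    A = _as_sparse(A)
    u, v = A.shape
    mse = _sq_frobenius(A, W, H, float((A.data**2).sum())) / (u * v)

    coo = A.tocoo()
    b_nz = np.einsum("ij,ij->i", W[coo.row], H[:, coo.col].T)
    b_nz = np.maximum(b_nz, _DIV_EPS)
    a = coo.data
    kl = float(np.sum(a * np.log(a / b_nz) - a))
    kl += float(W.sum(axis=0) @ H.sum(axis=1))  # sum of all WH cells
    return {"mse": mse, "kl_divergence": max(kl, 0.0)}


def _condition_assignments(runs: list[FactorizationResult]) -> np.ndarray:
    """Per run, each condition's cluster = argmax of its H column."""
    return np.stack([np.argmax(r.H, axis=0) for r in runs])


def cophenetic_coefficient(runs: list[FactorizationResult]) -> float:
    """Cophenetic correlation of the condition co-assignment consensus.

    The consensus matrix holds, for each pair of conditions, the fraction
    of runs assigning both to the same cluster.  Average-linkage clustering
    of 1 - consensus gives cophenetic distances whose Pearson correlation
    with the consensus distances measures how tree-like (stable) the
    consensus is.  A constant consensus (all runs identical) returns 1.
    """
    if len(runs) < 2:
        raise NMFError("cophenetic coefficient needs at least 2 runs")
    assigns = _condition_assignments(runs)  # n_runs x v
    n_runs, v = assigns.shape
    same = np.zeros((v, v))
    for row in assigns:
        same += row[:, None] == row[None, :]
    consensus = same / n_runs
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if len(condensed) else 0.0):
        return 1.0
    Z = average(condensed)
    c, _ = cophenet(Z, condensed)
    return float(c)


def rank_scan(
    A,
    k_range: tuple[int, int],
    runs_per_k: int = 10,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> RankScanReport:
    """Scan candidate ranks, recording best-run fit and inter-run stability.

    For each k in the inclusive range, ``runs_per_k`` independent
    factorisations are run (each a single restart from its own seed); the
    report carries the best run's MSE and KL divergence plus the cophenetic
    correlation across the runs.
    """
    A = _as_sparse(A)
    k_lo, k_hi = k_range
    if not 1 <= k_lo <= k_hi <= min(A.shape):
        raise NMFError(f"k_range {k_range} outside [1, {min(A.shape)}]")
    records = []
    for k in range(k_lo, k_hi + 1):
        runs = [
            factorize(
                A, k, n_restarts=1, max_iter=max_iter, tol=tol,
                seed=seed + 10_000 * k + r,
            )
            for r in range(runs_per_k)
        ]
        best = min(runs, key=lambda r: r.loss)
        metrics = fit_metrics(A, best.W, best.H)
        coph = cophenetic_coefficient(runs) if len(runs) >= 2 else float("nan")
        records.append(
            {
                "k": k,
                "mse": metrics["mse"],
                "kl_divergence": metrics["kl_divergence"],
                "cophenetic": coph,
                "runs_used": len(runs),
            }
        )
    return RankScanReport(records=records, k_range=(k_lo, k_hi))
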